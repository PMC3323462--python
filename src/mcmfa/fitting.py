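"""Fitting fluxes to measured mass distributions.

The inverse problem: find the steady-state flux distribution whose simulated
fragment MDVs best match measured ones,

    Error(v) = sum_i (fragment_i(v) - measured_i)^2 / sigma_i^2,

minimized over null-space coordinates a with v = v0 + N a and
v_min <= v <= v_max, so the mass-balance equalities hold by construction and
the variable count drops from the number of reactions to the degrees of
freedom.  The objective has local minima, so the optimizer is restarted from
many sampled interior points and the lowest minimum kept.

Per-reaction confidence intervals follow from re-optimizing each flux up and
down subject to Error(v) staying within an error budget (default 30 units)
above the minimum.

The API follows the model/results convention: ``FluxFit`` holds the data and
network, ``.fit()`` returns a ``FluxFitResults`` carrying estimates,
diagnostics, ``summary()`` and ``conf_int()``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import minimize

from .isotopomer import (FragmentDefinition, SimulationError, SubstrateMixture,
                         build_emu_network, simulate_emu)
from .network import AtomMappedNetwork, effective_null_space
from .sampler import generate_warmup, sample_flux_space

#: default per-element measurement standard deviation (replicate-derived)
SIGMA_DEFAULT = 0.014

#: default error budget above the minimum for confidence intervals
DELTA_DEFAULT = 30.0

#: measured window: fragments compared on M+0 .. M+6 only
MAX_MASSES = 7

_PENALTY = 1e8  # objective value for flux vectors that cannot be simulated


class MeasuredMDVSet:
    """Measured fragment MDVs with per-element standard deviations."""

    def __init__(self, data: dict[str, tuple[np.ndarray, np.ndarray | float]],
                 default_sigma: float = SIGMA_DEFAULT):
        self.data: dict[str, tuple[np.ndarray, np.ndarray]] = {}
        for fid, entry in data.items():
            values, sigma = entry
            values = np.asarray(values, float)
            if (values < -0.02).any() or (values > 1.02).any():
                raise ValueError(
                    f"{fid}: MDV values outside post-correction range")
            sig = np.broadcast_to(
                np.asarray(sigma if sigma is not None else default_sigma,
                           float), values.shape).copy()
            if (sig <= 0).any():
                raise ValueError(f"{fid}: sigma must be positive")
            self.data[fid] = (values, sig)

    @property
    def fragment_ids(self) -> list[str]:
        return sorted(self.data)

    def __getitem__(self, fid):
        return self.data[fid]

    @classmethod
    def from_csv(cls, path, default_sigma: float = SIGMA_DEFAULT
                 ) -> "MeasuredMDVSet":
        """CSV columns: fragment_id, mass_shift, value, sigma (optional)."""
        df = pd.read_csv(path)
        out = {}
        for fid, grp in df.groupby("fragment_id"):
            grp = grp.sort_values("mass_shift")
            sig = (grp["sigma"].to_numpy(float)
                   if "sigma" in grp else default_sigma)
            out[str(fid)] = (grp["value"].to_numpy(float), sig)
        return cls(out, default_sigma)

    def to_csv(self, path) -> None:
        rows = []
        for fid in self.fragment_ids:
            vals, sig = self.data[fid]
            for m, (x, s) in enumerate(zip(vals, sig)):
                rows.append((fid, m, x, s))
        pd.DataFrame(rows, columns=["fragment_id", "mass_shift", "value",
                                    "sigma"]).to_csv(path, index=False)

    def merged(self, other: "MeasuredMDVSet") -> "MeasuredMDVSet":
        """Union of two datasets; duplicate fragment ids must not collide."""
        out = dict(self.data)
        for fid, entry in other.data.items():
            if fid in out:
                raise ValueError(f"fragment id collision: {fid}")
            out[fid] = entry
        return MeasuredMDVSet(out)


@dataclass
class ConfidenceInterval:
    reaction: str
    v_min: float
    v_max: float
    error_budget: float
    status: str  # converged | bound-limited | failed


class FluxFit:
    """Model object binding a network, measured data, and a substrate label.

    Parameters
    ----------
    net : AtomMappedNetwork
        Elementary (irreversible) atom-mapped network.
    data : MeasuredMDVSet
        Measured fragment MDVs; fragment ids must appear in ``fragments``.
    label : SubstrateMixture
        The substrate labeling the data were measured under.
    fragments : list of FragmentDefinition
        Definitions for every measured fragment.
    """

    def __init__(self, net: AtomMappedNetwork, data: MeasuredMDVSet,
                 label: SubstrateMixture,
                 fragments: list[FragmentDefinition]):
        self.net = net
        self.data = data
        self.label = label
        by_id = {f.id: f for f in fragments}
        missing = [fid for fid in data.fragment_ids if fid not in by_id]
        if missing:
            raise ValueError(f"no fragment definitions for {missing}")
        self.fragments = [by_id[fid] for fid in data.fragment_ids]
        self._emu = build_emu_network(net, self.fragments)
        # fixed-bound reactions are honored inside the basis itself, so the
        # optimizer never sees degenerate equality-like inequality pairs
        basis = effective_null_space(net)
        self.N, self.dof = basis.N, basis.dof
        self.lb, self.ub = net.bounds()
        from .network import _solve_lp
        self.v0 = _solve_lp(np.zeros(len(net.reactions)),
                            net.stoichiometric_matrix(), self.lb, self.ub).x

    # -- objective ------------------------------------------------------------

    def v_of_alpha(self, alpha: np.ndarray) -> np.ndarray:
        return self.v0 + self.N @ alpha

    def error_function(self, v: np.ndarray) -> float:
        """Chi-square-style misfit of simulated vs measured fragment MDVs."""
        mdvs = simulate_emu(self._emu, np.maximum(v, 0.0), self.label)
        total = 0.0
        for fid in self.data.fragment_ids:
            meas, sig = self.data[fid]
            sim = mdvs[fid][:MAX_MASSES][: len(meas)]
            m = min(len(sim), len(meas))
            total += float(np.sum(((sim[:m] - meas[:m]) / sig[:m]) ** 2))
        return total

    def _objective(self, alpha: np.ndarray) -> float:
        v = self.v_of_alpha(alpha)
        if (v < self.lb - 1e-6).any() or (v > self.ub + 1e-6).any():
            # quadratic penalty keeps line searches informative off-polytope
            viol = (np.maximum(self.lb - v, 0) ** 2
                    + np.maximum(v - self.ub, 0) ** 2).sum()
            return _PENALTY * (1 + viol)
        try:
            return self.error_function(np.clip(v, self.lb, self.ub))
        except SimulationError:
            return _PENALTY

    def _bound_constraints(self):
        # linear in alpha: [N; -N] a <= [ub - v0; v0 - lb]; rows that cannot
        # bind along basis directions (fixed-bound reactions) are dropped,
        # they would otherwise act as spurious active equalities
        A = np.vstack([self.N, -self.N])
        b = np.concatenate([self.ub - self.v0, self.v0 - self.lb])
        keep = np.abs(A).max(axis=1) > 1e-12
        A, b = A[keep], b[keep]
        return [{"type": "ineq",
                 "fun": lambda a: b - A @ a,
                 "jac": lambda a: -A}]

    # -- fitting --------------------------------------------------------------

    def fit(self, n_restarts: int = 20, seed: int = 0,
            sampler_steps: int = 50) -> "FluxFitResults":
        """Multi-start local minimization over null-space coordinates.

        Restart points are interior samples of the flux polytope; the lowest
        local minimum is returned.  Deterministic under ``seed``.
        """
        rng = np.random.default_rng(seed)
        starts = sample_flux_space(
            self.net, n_points=max(n_restarts, 4), n_steps=sampler_steps,
            seed=int(rng.integers(2**31)))
        alphas = (starts.points[:n_restarts] - self.v0) @ self.N
        results = []
        for a0 in alphas:
            res = minimize(self._objective, a0, method="SLSQP",
                           constraints=self._bound_constraints(),
                           options={"maxiter": 300, "ftol": 1e-12})
            results.append(res)
        errors = [float(r.fun) for r in results]
        if all(e >= _PENALTY for e in errors):
            raise RuntimeError(
                f"all {n_restarts} restarts failed; errors={errors}")
        best = results[int(np.argmin(errors))]
        alpha_star = best.x
        v_star = np.clip(self.v_of_alpha(alpha_star), self.lb, self.ub)
        return FluxFitResults(self, alpha_star, v_star,
                              self.error_function(np.maximum(v_star, 0)),
                              len(results), errors, seed)


class FluxFitResults:
    """Best-fit fluxes, misfit, and interval machinery for a FluxFit."""

    def __init__(self, model: FluxFit, alpha_star, v_star, error_star,
                 n_restarts, restart_errors, seed):
        self.model = model
        self.alpha_star = np.asarray(alpha_star, float)
        self.v_star = np.asarray(v_star, float)
        self.error_star = float(error_star)
        self.n_restarts = int(n_restarts)
        self.restart_errors = list(restart_errors)
        self.seed = seed

    @property
    def fluxes(self) -> pd.Series:
        return pd.Series(self.v_star, index=self.model.net.reaction_ids,
                         name="flux")

    def conf_int(self, reaction: str, delta: float = DELTA_DEFAULT
                 ) -> ConfidenceInterval:
        """[v_min, v_max] for one reaction at an error budget.

        Minimizes/maximizes the reaction flux subject to the bounds and
        Error(v) <= Error_min + delta, starting from the best fit.  The
        returned interval always contains the best-fit value.
        """
        m = self.model
        j = m.net.reaction_ids.index(reaction)
        budget = self.error_star + delta
        cons = m._bound_constraints() + [
            {"type": "ineq", "fun": lambda a: budget - m._objective(a)},
        ]
        c = m.N[j]  # gradient of v_j wrt alpha

        vals, ok = [], True
        for sign in (+1.0, -1.0):
            res = minimize(lambda a: sign * float(m.v_of_alpha(a)[j]),
                           self.alpha_star, jac=lambda a: sign * c,
                           method="SLSQP", constraints=cons,
                           options={"maxiter": 200, "ftol": 1e-10})
            feasible = (m._objective(res.x) <= budget + 1e-6 * max(budget, 1))
            if not feasible:
                ok = False
                vals.append(self.v_star[j])
            else:
                vals.append(float(m.v_of_alpha(res.x)[j]))
        lo = min(vals + [self.v_star[j]])
        hi = max(vals + [self.v_star[j]])
        lo, hi = max(lo, m.lb[j]), min(hi, m.ub[j])
        status = "converged" if ok else "failed"
        if abs(lo - m.lb[j]) < 1e-9 or abs(hi - m.ub[j]) < 1e-9:
            status = "bound-limited" if ok else status
        return ConfidenceInterval(reaction, lo, hi, delta, status)

    def conf_int_table(self, reactions=None, delta: float = DELTA_DEFAULT
                       ) -> pd.DataFrame:
        reactions = reactions or self.model.net.reaction_ids
        rows = []
        for rid in reactions:
            ci = self.conf_int(rid, delta)
            rows.append((rid, self.fluxes[rid], ci.v_min, ci.v_max,
                         ci.v_max - ci.v_min, ci.status))
        return pd.DataFrame(rows, columns=["reaction", "v_star", "v_min",
                                           "v_max", "width", "status"]
                            ).set_index("reaction")

    def summary(self) -> str:
        m = self.model
        lines = [
            "Flux fit results",
            "=" * 48,
            f"Network:            {m.net.id}",
            f"Reactions:          {len(m.net.reactions)}",
            f"Degrees of freedom: {m.dof}",
            f"Fragments fitted:   {len(m.fragments)}",
            f"Restarts:           {self.n_restarts}",
            f"Minimum error:      {self.error_star:.6g}",
            f"Restart error span: [{min(self.restart_errors):.4g}, "
            f"{max(self.restart_errors):.4g}]",
            "-" * 48,
        ]
        for rid, val in self.fluxes.items():
            lines.append(f"{rid:<24s} {val:12.6f}")
        return "\n".join(lines)


def confidence_curve(
    interval_sets: dict[str, dict[str, tuple[float, float]]],
    widths: np.ndarray | None = None,
) -> pd.DataFrame:
    """Reactions resolved to a given confidence, per dataset combination.

    ``interval_sets`` maps a dataset-combination name to per-reaction
    (v_min, v_max) intervals.  Returns cumulative counts of reactions whose
    interval width is at or below each width; richer data never lowers the
    count at a fixed width.
    """
    all_widths = []
    for ivs in interval_sets.values():
        all_widths.extend(hi - lo for lo, hi in ivs.values())
    if widths is None:
        widths = np.unique(np.round(sorted(all_widths), 9))
    rows = {}
    for name, ivs in interval_sets.items():
        w = np.array([hi - lo for lo, hi in ivs.values()])
        rows[name] = [int(np.sum(w <= x + 1e-12)) for x in widths]
    return pd.DataFrame(rows, index=pd.Index(widths, name="width"))
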