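"""Uniform sampling of the steady-state flux polytope.

The feasible set {v : S v = 0, v_min <= v <= v_max} is a bounded convex
polytope.  Sampling is done with artificially-centered hit-and-run (ACHR):
a population of points is moved in place, one point per step, along chord
directions drawn from the spread of the population itself (random point
minus running center).  Because metabolic polytopes are typically elongated,
these self-tuned directions mix far faster than isotropic ones.

All moves are made in null-space coordinates v = v0 + N a, so the equality
constraints S v = 0 hold to machine precision by construction; only the
box bounds need chord intersection.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .network import (AtomMappedNetwork, InfeasibleError,
                      effective_null_space, _solve_lp)


class DegeneratePolytopeError(RuntimeError):
    """The flux space has no free dimensions (dof = 0)."""


@dataclass
class FluxSampleSet:
    """A set of steady-state flux vectors (rows) from the sampler."""

    points: np.ndarray  # (n_points, n_reactions)
    reaction_ids: list[str]
    seed: int
    n_steps_per_point: int
    network_id: str = "network"

    @property
    def n_points(self) -> int:
        return self.points.shape[0]

    def column(self, reaction_id: str) -> np.ndarray:
        return self.points[:, self.reaction_ids.index(reaction_id)]

    def validate(self, net: AtomMappedNetwork,
                 steady_tol: float = 1e-6, bound_tol: float = 1e-9) -> None:
        S = net.stoichiometric_matrix()
        lb, ub = net.bounds()
        resid = np.abs(S @ self.points.T)
        if resid.size and resid.max() > steady_tol:
            raise AssertionError(f"steady-state violated: {resid.max():.2e}")
        if (self.points < lb - bound_tol).any() or (self.points > ub + bound_tol).any():
            raise AssertionError("bound violation in sample set")

    def to_dataframe(self):
        import pandas as pd

        return pd.DataFrame(self.points, columns=self.reaction_ids)

    def save_csv(self, path) -> None:
        self.to_dataframe().to_csv(path, index=False)

    def save_hdf5(self, path) -> None:
        import h5py

        with h5py.File(path, "w") as f:
            f.create_dataset("points", data=self.points)
            f.create_dataset(
                "reaction_ids",
                data=np.array(self.reaction_ids, dtype="S"))
            f.attrs["seed"] = self.seed
            f.attrs["n_steps_per_point"] = self.n_steps_per_point
            f.attrs["network_id"] = self.network_id

    @classmethod
    def load_hdf5(cls, path) -> "FluxSampleSet":
        import h5py

        with h5py.File(path, "r") as f:
            return cls(
                points=f["points"][...],
                reaction_ids=[s.decode() for s in f["reaction_ids"][...]],
                seed=int(f.attrs["seed"]),
                n_steps_per_point=int(f.attrs["n_steps_per_point"]),
                network_id=str(f.attrs["network_id"]),
            )


def _polytope(net: AtomMappedNetwork):
    """Return (v0, N, A, b) with the feasible set as {a : A a <= b} around a
    feasible anchor v0."""
    S = net.stoichiometric_matrix()
    lb, ub = net.bounds()
    # basis respecting bound-fixed reactions, so every direction stays in
    # the affine hull of the feasible set
    basis = effective_null_space(net)
    if basis.dof == 0:
        raise DegeneratePolytopeError(
            "flux space is zero-dimensional (dof = 0); nothing to sample")
    n = len(net.reactions)
    v0 = _solve_lp(np.zeros(n), S, lb, ub).x
    N = basis.N
    A = np.vstack([N, -N])
    b = np.concatenate([ub - v0, v0 - lb])
    if (b < -1e-9).any():
        raise InfeasibleError("anchor point violates bounds")
    # rows that can never bind along hull directions are dropped for chord
    # robustness
    keep = np.abs(A).max(axis=1) > 1e-12
    return v0, N, A[keep], b[keep]


def generate_warmup(
    net: AtomMappedNetwork, n_points: int, seed: int,
    shrink: float = 0.95,
) -> FluxSampleSet:
    """LP-optimal vertices in random objective directions, shrunk toward
    their centroid so every warmup point is strictly interior."""
    rng = np.random.default_rng(seed)
    v0, N, A, b = _polytope(net)
    dof = N.shape[1]
    alphas = np.empty((n_points, dof))
    from scipy.optimize import linprog

    for k in range(n_points):
        if k < 2 * dof:
            # +/- coordinate directions first: guarantees the warmup spans
            # the polytope's affine hull even for small n_points
            c = np.zeros(dof)
            c[k // 2] = 1.0 if k % 2 == 0 else -1.0
        else:
            c = rng.standard_normal(dof)
        res = linprog(-c, A_ub=A, b_ub=b, bounds=[(None, None)] * dof,
                      method="highs")
        if res.status == 2:
            raise InfeasibleError("warmup LP infeasible")
        if not res.success:
            raise RuntimeError(f"warmup LP failed: {res.message}")
        alphas[k] = res.x
    centroid = alphas.mean(axis=0)
    alphas = centroid + shrink * (alphas - centroid)
    pts = v0 + alphas @ N.T
    return FluxSampleSet(pts, net.reaction_ids, seed, 0, net.id)


def _chord(A, b, x, d, guard: float = 1e-8):
    """Intersection [lo, hi] of the line x + t d with {A y <= b}.

    Returns None when the chord is numerically empty.
    """
    Ad = A @ d
    slack = b - A @ x
    slack = np.maximum(slack, 0.0)  # clamp tiny negative slack on the boundary
    with np.errstate(divide="ignore"):
        pos = Ad > 1e-12
        neg = Ad < -1e-12
        hi = np.min(slack[pos] / Ad[pos]) if pos.any() else np.inf
        lo = np.max(slack[neg] / Ad[neg]) if neg.any() else -np.inf
    if not np.isfinite(hi) or not np.isfinite(lo):
        return None  # unbounded direction (should not happen on capped nets)
    width = hi - lo
    if width <= 0:
        return None
    return lo + guard * width, hi - guard * width


def sample_flux_space(
    net: AtomMappedNetwork,
    n_points: int = 100,
    n_steps: int = 200,
    seed: int = 0,
    warmup: FluxSampleSet | None = None,
    mixing_warn_threshold: float = 0.2,
    max_retries: int = 50,
) -> FluxSampleSet:
    """ACHR sampling: ``n_points`` population members, each moved ``n_steps``
    times in place.

    Each step picks the next population member, draws a direction from the
    running center to a random member, intersects that line with the
    polytope, and relocates the member uniformly on the chord.  The running
    center is updated incrementally after every accepted move.  Identical
    (seed, inputs) give identical output.
    """
    rng = np.random.default_rng(seed)
    v0, N, A, b = _polytope(net)
    dof = N.shape[1]
    if warmup is None:
        n_warm = max(n_points, 2 * dof)
        warm = generate_warmup(net, n_warm, seed=int(rng.integers(2**31)))
    else:
        warm = warmup
    # express warmup in null-space coordinates
    X = (warm.points - v0) @ N  # (n_warm, dof); N orthonormal
    if X.shape[0] >= n_points:
        X = X[:n_points].copy()
    else:
        reps = rng.integers(0, X.shape[0], size=n_points - X.shape[0])
        X = np.vstack([X, X[reps]])
    center = X.mean(axis=0)
    n_pop = X.shape[0]
    for step in range(n_steps):
        for i in range(n_pop):
            moved = False
            for _ in range(max_retries):
                j = int(rng.integers(n_pop))
                d = X[j] - center
                norm = np.linalg.norm(d)
                if norm < 1e-12:
                    continue
                d = d / norm
                span = _chord(A, b, X[i], d)
                if span is None:
                    continue
                lo, hi = span
                t = rng.uniform(lo, hi)
                new = X[i] + t * d
                center = center + (new - X[i]) / n_pop
                X[i] = new
                moved = True
                break
            if not moved:
                raise RuntimeError(
                    f"no valid chord found for point {i} after "
                    f"{max_retries} retries")
    pts = v0 + X @ N.T
    out = FluxSampleSet(pts, net.reaction_ids, seed, n_steps, net.id)
    out.validate(net)
    _mixing_check(out, mixing_warn_threshold)
    return out


def _mixing_check(samples: FluxSampleSet, threshold: float) -> None:
    """Split-half comparison of per-reaction means; warns on poor mixing."""
    half = samples.n_points // 2
    if half < 2:
        return
    m1 = samples.points[:half].mean(axis=0)
    m2 = samples.points[half:].mean(axis=0)
    scale = np.abs(samples.points).mean(axis=0) + 1e-9
    rel = np.abs(m1 - m2) / scale
    if rel.max() > threshold:
        warnings.warn(
            f"split-half means differ by up to {rel.max():.2f} (relative); "
            "consider more steps", RuntimeWarning)
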