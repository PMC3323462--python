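"""Generated toy networks, brute-force oracles, and synthetic measurements.

Every topology here is a small atom-mapped network exercising one structural
feature of real metabolic networks: linear chains, branch points with
distinguishable carbon fates, condensations, reversible exchange, parallel
pathways with identical atom maps (structurally unidentifiable), and a
pentose-phosphate-like branch where one route loses carbon 1 to an untracked
sink while the other keeps it — the situation that makes positional labels
informative about branch ratios.

The brute-force solver assembles the full nonlinear isotopomer balance
system and solves it by fixed-point iteration; it is the reference against
which the EMU and cumomer routes are checked.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .fitting import MeasuredMDVSet
from .isotopomer import (FragmentDefinition, SubstrateMixture,
                         _is_input_map, _producer_index,
                         prune_zero_flux_components, simulate_fragments)
from .network import AtomMappedNetwork, decompose_reversible

TOPOLOGIES = (
    "chain", "diamond", "condensation", "self_condensation",
    "reversible_loop", "unidentifiable_parallel", "parallel3",
    "simplex", "ppp_branch",
)


@dataclass
class FixtureSpec:
    name: str
    n_mets: int = 3
    n_carbons: int = 2
    seed: int = 0
    noise_sigma: float = 0.014


def _rows_for(name: str, n_mets: int, n_carbons: int):
    letters = "abcdefgh"

    if name == "chain":
        g = letters[:n_carbons]
        mets = [chr(ord("A") + i) for i in range(n_mets)]
        rows = [("IN", f"-> {mets[0]}", f"-> {g}", 0, 10, "exchange")]
        for i in range(n_mets - 1):
            rows.append((f"R{i+1}", f"{mets[i]} -> {mets[i+1]}",
                         f"{g} -> {g}", 0, 10, "chain"))
        rows.append(("OUT", f"{mets[-1]} ->", f"{g} ->", 0, 10, "exchange"))
        return rows

    if name == "diamond":
        # the two branches route carbons differently, so they are
        # distinguishable by labeling
        return [
            ("IN", "-> A", "-> ab", 1, 1, "exchange"),
            ("R1", "A -> B", "ab -> ab", 0, 10, "branch1"),
            ("R2", "A -> C", "ab -> ba", 0, 10, "branch2"),
            ("R3", "B -> D", "ab -> ab", 0, 10, "branch1"),
            ("R4", "C -> D", "ab -> ab", 0, 10, "branch2"),
            ("OUT", "D ->", "ab ->", 0, 10, "exchange"),
        ]

    if name == "condensation":
        return [
            ("AIN", "-> A", "-> ab", 0, 10, "exchange"),
            ("BIN", "-> B", "-> ab", 0, 10, "exchange"),
            ("C1", "A + B -> P", "ab + cd -> abcd", 0, 10, "condensation"),
            ("OUT", "P ->", "abcd ->", 0, 10, "exchange"),
        ]

    if name == "self_condensation":
        return [
            ("AIN", "-> A", "-> ab", 0, 10, "exchange"),
            ("C1", "2 A -> P", "ab + cd -> abcd", 0, 10, "condensation"),
            ("OUT", "P ->", "abcd ->", 0, 10, "exchange"),
        ]

    if name == "reversible_loop":
        return [
            ("IN", "-> A", "-> ab", 0, 10, "exchange"),
            ("R1", "A -> B", "ab -> ba", -10, 10, "reversible"),
            ("R2", "B -> C", "ab -> ab", 0, 10, "chain"),
            ("OUT", "C ->", "ab ->", 0, 10, "exchange"),
        ]

    if name == "unidentifiable_parallel":
        # two branches with identical atom maps: only their sum is
        # observable from labeling data
        return [
            ("IN", "-> A", "-> ab", 0, 10, "exchange"),
            ("R1", "A -> B", "ab -> ab", 0, 10, "branch1"),
            ("R2", "A -> B", "ab -> ab", 0, 10, "branch2"),
            ("OUT", "B ->", "ab ->", 0, 10, "exchange"),
        ]

    if name == "parallel3":
        # three capped parallel branches with a capped total: the feasible
        # set projects onto the unit cube cut by R1+R2+R3 <= 2 - a clean
        # 3-dof sampling target with a nontrivial shape
        return [
            ("IN", "-> A", "-> ab", 0, 2, "exchange"),
            ("R1", "A -> B", "ab -> ab", 0, 1, "branch"),
            ("R2", "A -> B", "ab -> ba", 0, 1, "branch"),
            ("R3", "A -> B", "ab -> ab", 0, 1, "branch"),
            ("OUT", "B ->", "ab ->", 0, 10, "exchange"),
        ]

    if name == "simplex":
        # fixed input split over two drains: v_R1 + v_R2 = 1
        return [
            ("IN", "-> A", "-> ab", 1, 1, "exchange"),
            ("R1", "A ->", "ab ->", 0, 10, "drain"),
            ("R2", "A ->", "ab ->", 0, 10, "drain"),
        ]

    if name == "ppp_branch":
        # branch 1 loses carbon 1 to an untracked sink (like the oxidative
        # PPP decarboxylation); branch 2 keeps carbons 1,2.  A label on
        # carbon 1 separates the branches; a label on carbon 2 does not.
        return [
            ("IN", "-> A", "-> abc", 1, 1, "exchange"),
            ("PPP", "A -> B", "abc -> bc", 0, 10, "ppp"),
            ("GLY", "A -> B", "abc -> ab", 0, 10, "glycolysis"),
            ("OUT", "B ->", "ab ->", 0, 10, "exchange"),
        ]

    raise ValueError(f"unknown topology {name!r}")


def make_toy_network(spec: FixtureSpec | str) -> AtomMappedNetwork:
    """Build one of the named toy topologies (deterministic)."""
    if isinstance(spec, str):
        spec = FixtureSpec(spec)
    rows = _rows_for(spec.name, spec.n_mets, spec.n_carbons)
    return AtomMappedNetwork.from_rows(rows, id=spec.name)


def default_fragments(net: AtomMappedNetwork) -> list[FragmentDefinition]:
    """Full-carbon fragment for every tracked sink-ish metabolite; for the
    oracle comparisons a fragment per tracked metabolite is generated."""
    out = []
    for m in net.metabolites.values():
        if m.tracked:
            out.append(FragmentDefinition(
                id=f"{m.id}_full", metabolite=m.id,
                carbons=tuple(range(1, m.n_carbons + 1))))
    return out


# -- brute-force isotopomer oracle -------------------------------------------


def brute_force_isotopomer_solve(
    net: AtomMappedNetwork,
    v: np.ndarray,
    label: SubstrateMixture,
    tol: float = 1e-12,
    max_iter: int = 100_000,
    init: str = "unlabeled",
) -> dict[str, np.ndarray]:
    """Solve the full nonlinear isotopomer balances by fixed-point iteration.

    Desk-scale guard: at most 4096 isotopomer variables.  Serves as the
    independent oracle for the EMU and cumomer solvers.
    """
    v = np.asarray(v, float)
    tracked = [m for m in net.metabolites.values() if m.tracked]
    if sum(2 ** m.n_carbons for m in tracked) > 4096:
        raise ValueError("brute-force oracle limited to 4096 isotopomers")
    producers = _producer_index(net)
    active, _, _ = prune_zero_flux_components(net, v)
    n_carb = {m.id: m.n_carbons for m in tracked}
    sources = {m for m in active if m not in producers}

    idv: dict[str, np.ndarray] = {}
    for met in active:
        n = n_carb[met]
        if met in sources:
            idv[met] = label.idv(met, n)
        elif init == "unlabeled":
            x = np.zeros(1 << n)
            x[0] = 1.0
            idv[met] = x
        else:  # uniform initialization (used to probe uniqueness)
            idv[met] = np.full(1 << n, 1.0 / (1 << n))

    internal = [m for m in active if m not in sources]

    def production_idv(met: str) -> np.ndarray:
        n = n_carb[met]
        acc = np.zeros(1 << n)
        total = 0.0
        for j, pi in producers[met]:
            if v[j] < 1e-12:
                continue
            r = net.reactions[j]
            if _is_input_map(r):
                acc += v[j] * label.idv(met, n)
                total += v[j]
                continue
            amap = r.atom_map
            _, prod_letters = amap.products[pi]
            letter_src = {}
            for si, (smet, g) in enumerate(amap.substrates):
                for k, ch in enumerate(g):
                    letter_src[ch] = (si, k)
            term = np.zeros(1 << n)
            for iso in range(1 << n):
                # per substrate instance: positions that must match
                conds: dict[int, tuple[int, int]] = {}
                for p in range(n):
                    si, sp = letter_src[prod_letters[p]]
                    cm, cv = conds.get(si, (0, 0))
                    cm |= 1 << sp
                    if (iso >> p) & 1:
                        cv |= 1 << sp
                    conds[si] = (cm, cv)
                pr = 1.0
                for si, (cm, cv) in conds.items():
                    smet = amap.substrates[si][0]
                    s_idv = idv[smet]
                    pr *= float(sum(
                        s_idv[k] for k in range(len(s_idv))
                        if (k & cm) == cv))
                term[iso] = pr
            acc += v[j] * term
            total += v[j]
        return acc / total

    for _ in range(max_iter):
        delta = 0.0
        for met in internal:
            new = production_idv(met)
            delta = max(delta, float(np.abs(new - idv[met]).max()))
            idv[met] = new
        if delta < tol:
            break
    else:
        raise RuntimeError("brute-force iteration did not converge")
    return idv


# -- synthetic measurements ---------------------------------------------------


def simulate_measured_dataset(
    net: AtomMappedNetwork,
    v_true: np.ndarray,
    label: SubstrateMixture,
    fragments: list[FragmentDefinition],
    sigma: float = 0.014,
    seed: int = 0,
) -> MeasuredMDVSet:
    """Noisy synthetic measurements: simulated MDVs + i.i.d. Gaussian noise,
    clipped and renormalized (seed-deterministic)."""
    rng = np.random.default_rng(seed)
    mdvs = simulate_fragments(net, v_true, label, fragments)
    out = {}
    for fid, mdv in mdvs.items():
        noisy = mdv + rng.normal(0.0, sigma, size=mdv.shape) if sigma > 0 \
            else mdv.copy()
        noisy = np.clip(noisy, 0.0, None)
        noisy = noisy / noisy.sum()
        # sigma = 0 means exact data; keep the default measurement sigma in
        # the weighting so the fit objective stays well-scaled
        out[fid] = (noisy, sigma if sigma > 0 else 0.014)
    return MeasuredMDVSet(out)


def elementary(net_or_name) -> AtomMappedNetwork:
    """Toy network in elementary (fully irreversible) form."""
    net = (make_toy_network(net_or_name)
           if isinstance(net_or_name, (str, FixtureSpec)) else net_or_name)
    return decompose_reversible(net)
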