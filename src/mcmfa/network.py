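"""Atom-mapped stoichiometric networks and their linear analysis.

A network couples ordinary constraint-based stoichiometry (S, flux bounds)
with per-reaction carbon transition maps, which record, for every carbon of
every product, the substrate carbon it came from.  The carbon-map dialect is
FTBL-like: one lowercase letter per carbon, with substrate-side letter groups
mapping onto product-side groups, e.g. ``abc -> ab + c`` for a C3 compound
split into a C2 and a C1 product.  Letters appearing on the substrate side
but not the product side are carbons lost to untracked sinks (e.g. CO2) and
are recorded explicitly.

Carbon positions are 1-based throughout (chemistry convention); the letter at
string index k-1 is carbon k of that metabolite instance.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field, replace

import numpy as np
from scipy import linalg
from scipy.optimize import linprog

#: Cap applied to infinite bounds before LP / sampling (mmol gDW^-1 h^-1).
#: Hit-and-run sampling requires a bounded polytope.
BOUND_CAP = 1000.0

#: Singular values below RANK_TOL * (largest singular value) are treated as
#: zero when computing rank and null space.
RANK_TOL = 1e-9


class NetworkError(ValueError):
    """Malformed network definition (parse or validation failure)."""


class InfeasibleError(RuntimeError):
    """The constraint set {S v = 0, v_min <= v <= v_max} is empty."""


@dataclass
class Metabolite:
    id: str
    n_carbons: int = 0
    tracked: bool = False
    is_boundary: bool = False


@dataclass
class CarbonTransition:
    """Letter-group atom map for one reaction.

    ``substrates`` / ``products`` are lists of (metabolite_id, letters),
    one entry per metabolite *instance* (a stoichiometric coefficient of 2
    contributes two instances).  Untracked instances carry an empty string.
    ``lost`` holds the substrate letters that do not reappear on the product
    side.
    """

    substrates: list[tuple[str, str]]
    products: list[tuple[str, str]]
    lost: str = ""

    def mirrored(self) -> "CarbonTransition":
        if self.lost:
            raise NetworkError(
                "cannot mirror an atom map that loses carbons; "
                "reversible reactions must conserve tracked carbon"
            )
        return CarbonTransition(
            substrates=list(self.products),
            products=list(self.substrates),
            lost="",
        )


@dataclass
class Reaction:
    id: str
    stoichiometry: dict[str, float]
    lower_bound: float = 0.0
    upper_bound: float = BOUND_CAP
    subsystem: str = ""
    atom_map: CarbonTransition | None = None

    @property
    def reversible(self) -> bool:
        return self.lower_bound < 0

    @property
    def tracks_carbon(self) -> bool:
        return self.atom_map is not None


@dataclass
class NullSpaceBasis:
    N: np.ndarray  # (n_reactions, dof), orthonormal columns
    dof: int


def _parse_equation(text: str) -> tuple[list[tuple[str, float]], list[tuple[str, float]]]:
    """Parse ``a + 2 b -> c`` into (substrate, coeff) and (product, coeff) lists."""
    if "->" not in text:
        raise NetworkError(f"equation missing '->': {text!r}")
    lhs, rhs = text.split("->", 1)

    def side(s: str) -> list[tuple[str, float]]:
        out: list[tuple[str, float]] = []
        s = s.strip()
        if not s:
            return out
        for term in s.split("+"):
            term = term.strip()
            if not term:
                raise NetworkError(f"empty term in equation {text!r}")
            m = re.match(r"^(\d+(?:\.\d+)?)\s+(\S+)$", term)
            if m:
                out.append((m.group(2), float(m.group(1))))
            else:
                out.append((term, 1.0))
        return out

    return side(lhs), side(rhs)


def _expand_instances(side: list[tuple[str, float]]) -> list[str]:
    """Expand stoichiometric multiplicity into a per-instance metabolite list.

    Non-integer coefficients cannot carry atom maps and yield no instances
    beyond the integer part paired with groups (they are rejected later if a
    map references them).
    """
    out = []
    for met, coeff in side:
        n = int(round(coeff))
        if abs(coeff - n) > 1e-9:
            raise NetworkError(
                f"non-integer coefficient {coeff} for {met} in a mapped reaction"
            )
        out.extend([met] * n)
    return out


def parse_carbon_transition(
    equation: str, transition: str
) -> CarbonTransition:
    """Parse a transition string against its reaction equation.

    Groups align positionally with the metabolite instances on each side of
    the equation; ``-`` marks a carbon-free (untracked) instance.
    """
    subs, prods = _parse_equation(equation)
    t = transition.replace("→", "->")
    if "->" not in t:
        raise NetworkError(f"transition missing '->': {transition!r}")
    tl, tr = t.split("->", 1)

    def groups(s: str) -> list[str]:
        s = s.strip()
        if not s:
            return []
        return [g.strip() for g in s.split("+")]

    gl, gr = groups(tl), groups(tr)
    sub_insts, prod_insts = _expand_instances(subs), _expand_instances(prods)
    if len(gl) != len(sub_insts) or len(gr) != len(prod_insts):
        raise NetworkError(
            f"transition groups do not align with equation instances: "
            f"{transition!r} vs {equation!r}"
        )

    def pair(insts: list[str], grps: list[str], side: str) -> list[tuple[str, str]]:
        out = []
        for met, g in zip(insts, grps):
            if g == "-":
                g = ""
            if not re.fullmatch(r"[a-z]*", g):
                raise NetworkError(
                    f"malformed carbon group {g!r} in {transition!r} "
                    "(one lowercase letter per carbon)"
                )
            out.append((met, g))
        letters = "".join(g for _, g in out)
        if len(set(letters)) != len(letters):
            raise NetworkError(
                f"duplicate carbon letters on {side} side of {transition!r}"
            )
        return out

    sub_pairs = pair(sub_insts, gl, "substrate")
    prod_pairs = pair(prod_insts, gr, "product")
    sub_letters = set("".join(g for _, g in sub_pairs))
    prod_letters = set("".join(g for _, g in prod_pairs))
    if sub_letters and not prod_letters <= sub_letters:
        raise NetworkError(
            f"product carbons {sorted(prod_letters - sub_letters)} have no "
            f"substrate source in {transition!r}"
        )
    # a transition with no substrate letters is a boundary input: its product
    # carbons enter from outside and the reaction does not determine labeling
    lost = "".join(sorted(sub_letters - prod_letters))
    return CarbonTransition(substrates=sub_pairs, products=prod_pairs, lost=lost)


class AtomMappedNetwork:
    """Stoichiometry + carbon maps + bounds; source of truth for S and v bounds."""

    def __init__(self, metabolites: list[Metabolite], reactions: list[Reaction],
                 id: str = "network"):
        self.id = id
        self.metabolites: dict[str, Metabolite] = {}
        for m in metabolites:
            if m.id in self.metabolites:
                raise NetworkError(f"duplicate metabolite id {m.id!r}")
            self.metabolites[m.id] = m
        self.reactions: list[Reaction] = []
        seen = set()
        for r in reactions:
            if r.id in seen:
                raise NetworkError(f"duplicate reaction id {r.id!r}")
            seen.add(r.id)
            self.reactions.append(r)
        #: original-reaction -> (forward id, reverse id), filled by decompose
        self.reversible_pairs: dict[str, tuple[str, str]] = {}
        self.validate()

    # -- construction helpers -------------------------------------------------

    @classmethod
    def from_rows(cls, rows, id: str = "network") -> "AtomMappedNetwork":
        """Build from (reaction_id, equation, transition, lower, upper, subsystem)
        rows; transition may be empty for untracked reactions."""
        mets: dict[str, Metabolite] = {}
        rxns = []
        for rid, eq, trans, lo, hi, subsystem in rows:
            subs, prods = _parse_equation(eq)
            stoich: dict[str, float] = {}
            for met, c in subs:
                stoich[met] = stoich.get(met, 0.0) - c
            for met, c in prods:
                stoich[met] = stoich.get(met, 0.0) + c
            amap = None
            if trans and trans.strip():
                amap = parse_carbon_transition(eq, trans)
                for met, g in amap.substrates + amap.products:
                    if not g:
                        continue
                    m = mets.setdefault(met, Metabolite(met))
                    if m.tracked and m.n_carbons != len(g):
                        raise NetworkError(
                            f"carbon-count mismatch for {met}: "
                            f"{m.n_carbons} vs {len(g)} in {rid}"
                        )
                    m.n_carbons = len(g)
                    m.tracked = True
            for met in stoich:
                mets.setdefault(met, Metabolite(met))
            rxns.append(Reaction(rid, stoich, float(lo), float(hi),
                                 subsystem or "", amap))
        return cls(list(mets.values()), rxns, id=id)

    # -- validation -----------------------------------------------------------

    def validate(self) -> None:
        for r in self.reactions:
            if r.lower_bound > r.upper_bound:
                raise NetworkError(f"{r.id}: lower bound exceeds upper bound")
            if r.atom_map is None:
                continue
            # every mapped instance must appear in stoichiometry with enough
            # multiplicity, and tracked carbon must be conserved
            for side, sign in ((r.atom_map.substrates, -1), (r.atom_map.products, +1)):
                counts: dict[str, int] = {}
                for met, g in side:
                    counts[met] = counts.get(met, 0) + 1
                    m = self.metabolites.get(met)
                    if g and (m is None or m.n_carbons != len(g)):
                        raise NetworkError(
                            f"{r.id}: atom map group for {met} has {len(g)} "
                            f"carbons but metabolite has "
                            f"{m.n_carbons if m else '?'}"
                        )
                for met, n in counts.items():
                    have = sign * r.stoichiometry.get(met, 0.0)
                    if have + 1e-9 < n:
                        raise NetworkError(
                            f"{r.id}: atom map uses {met} x{n} but "
                            f"stoichiometry provides {have}"
                        )
            n_in = sum(len(g) for _, g in r.atom_map.substrates)
            n_out = sum(len(g) for _, g in r.atom_map.products)
            if n_in and n_in != n_out + len(r.atom_map.lost):
                raise NetworkError(f"{r.id}: carbon balance violated")

    # -- linear structure -----------------------------------------------------

    @property
    def internal_metabolites(self) -> list[str]:
        return [m.id for m in self.metabolites.values() if not m.is_boundary]

    @property
    def reaction_ids(self) -> list[str]:
        return [r.id for r in self.reactions]

    def reaction(self, rid: str) -> Reaction:
        for r in self.reactions:
            if r.id == rid:
                return r
        raise KeyError(rid)

    def stoichiometric_matrix(self) -> np.ndarray:
        mets = self.internal_metabolites
        idx = {m: i for i, m in enumerate(mets)}
        S = np.zeros((len(mets), len(self.reactions)))
        for j, r in enumerate(self.reactions):
            for met, c in r.stoichiometry.items():
                if met in idx:
                    S[idx[met], j] = c
        return S

    @property
    def S(self) -> np.ndarray:
        return self.stoichiometric_matrix()

    def bounds(self, capped: bool = True) -> tuple[np.ndarray, np.ndarray]:
        lb = np.array([r.lower_bound for r in self.reactions], float)
        ub = np.array([r.upper_bound for r in self.reactions], float)
        if capped:
            lb = np.maximum(lb, -BOUND_CAP)
            ub = np.minimum(ub, BOUND_CAP)
        return lb, ub

    def net_fluxes(self, v: np.ndarray) -> dict[str, float]:
        """Per original-reaction net flux, recombining decomposed pairs."""
        vals = dict(zip(self.reaction_ids, v))
        out: dict[str, float] = {}
        paired = set()
        for orig, (f, b) in self.reversible_pairs.items():
            out[orig] = vals[f] - vals[b]
            paired.update((f, b))
        for rid, x in vals.items():
            if rid not in paired:
                out[rid] = x
        return out

    def summary(self) -> dict:
        tracked_mets = [m for m in self.metabolites.values() if m.tracked]
        return {
            "network_id": self.id,
            "n_reactions": len(self.reactions),
            "n_tracked_reactions": sum(r.tracks_carbon for r in self.reactions),
            "n_metabolites": len(self.metabolites),
            "n_tracked_metabolites": len(tracked_mets),
            "n_isotopomer_variables": int(
                sum(2 ** m.n_carbons for m in tracked_mets)
            ),
            "dof": compute_null_space(self).dof,
        }


# -- operations ---------------------------------------------------------------


def load_network(path, format: str = "atommap-tsv") -> AtomMappedNetwork:
    """Load a network from disk.

    "atommap-tsv" is tab-separated with columns
    [reaction_id, equation, carbon_transition, lower, upper, subsystem];
    lines starting with '#' (or a header line starting with 'reaction_id')
    are skipped.  "sbml" imports stoichiometry and bounds only (SBML has no
    standard carbon-map encoding); atom maps must come from a tabular file.
    """
    if format == "atommap-tsv":
        rows = []
        with open(path) as fh:
            for line in fh:
                line = line.rstrip("\n")
                if not line.strip() or line.startswith("#"):
                    continue
                parts = line.split("\t")
                if parts[0] == "reaction_id":
                    continue
                parts += [""] * (6 - len(parts))
                rid, eq, trans, lo, hi, subsystem = parts[:6]
                rows.append((rid, eq, trans,
                             float(lo) if lo else 0.0,
                             float(hi) if hi else BOUND_CAP,
                             subsystem))
        name = getattr(path, "stem", None) or str(path)
        return AtomMappedNetwork.from_rows(rows, id=name)
    if format == "sbml":
        import cobra

        model = cobra.io.read_sbml_model(str(path))
        mets = [Metabolite(m.id) for m in model.metabolites]
        rxns = [
            Reaction(r.id, {m.id: c for m, c in r.metabolites.items()},
                     r.lower_bound, r.upper_bound, r.subsystem or "")
            for r in model.reactions
        ]
        return AtomMappedNetwork(mets, rxns, id=model.id or str(path))
    raise ValueError(f"unknown format {format!r}")


def write_network(net: AtomMappedNetwork, path) -> None:
    """Write in the atommap-tsv dialect (round-trips with load_network)."""
    with open(path, "w") as fh:
        fh.write("reaction_id\tequation\tcarbon_transition\tlower\tupper\tsubsystem\n")
        for r in net.reactions:
            subs = [(m, -c) for m, c in r.stoichiometry.items() if c < 0]
            prods = [(m, c) for m, c in r.stoichiometry.items() if c > 0]

            def fmt(side):
                return " + ".join(
                    (f"{c:g} {m}" if abs(c - 1) > 1e-9 else m) for m, c in side
                )

            eq = f"{fmt(subs)} -> {fmt(prods)}"
            trans = ""
            if r.atom_map is not None:
                left = " + ".join(g or "-" for _, g in r.atom_map.substrates)
                right = " + ".join(g or "-" for _, g in r.atom_map.products)
                trans = f"{left} -> {right}" if right else f"{left} ->"
            fh.write(f"{r.id}\t{eq}\t{trans}\t{r.lower_bound:g}\t"
                     f"{r.upper_bound:g}\t{r.subsystem}\n")


def decompose_reversible(net: AtomMappedNetwork) -> AtomMappedNetwork:
    """Split every reversible reaction into elementary forward/reverse halves.

    The reverse half has negated stoichiometry, the mirrored atom map, and
    bounds [0, -original lower]; the mapping original -> (fwd, rev) is kept
    so net fluxes remain recoverable.
    """
    mets = [replace(m) for m in net.metabolites.values()]
    rxns: list[Reaction] = []
    pairs: dict[str, tuple[str, str]] = {}
    for r in net.reactions:
        if not r.reversible:
            rxns.append(replace(r))
            continue
        fwd = Reaction(r.id + "_f", dict(r.stoichiometry), 0.0,
                       max(r.upper_bound, 0.0), r.subsystem, r.atom_map)
        rev = Reaction(r.id + "_b",
                       {m: -c for m, c in r.stoichiometry.items()},
                       0.0, -r.lower_bound, r.subsystem,
                       r.atom_map.mirrored() if r.atom_map else None)
        rxns.extend([fwd, rev])
        pairs[r.id] = (fwd.id, rev.id)
    out = AtomMappedNetwork(mets, rxns, id=net.id)
    out.reversible_pairs = pairs
    return out


def compute_null_space(net: AtomMappedNetwork) -> NullSpaceBasis:
    S = net.stoichiometric_matrix()
    n = len(net.reactions)
    if S.size == 0:
        return NullSpaceBasis(np.eye(n), n)
    sv = linalg.svdvals(S)
    rcond = RANK_TOL
    N = linalg.null_space(S, rcond=rcond)
    rank = int(np.sum(sv > RANK_TOL * (sv[0] if sv.size else 1.0)))
    dof = n - rank
    # null_space's own thresholding matches ours for well-separated spectra
    assert N.shape[1] == dof, "rank tolerance disagreement"
    return NullSpaceBasis(N, dof)


def effective_null_space(
    net: AtomMappedNetwork, fixed_tol: float = 1e-9
) -> NullSpaceBasis:
    """Null-space basis that also respects bound-fixed reactions.

    Reactions with upper - lower <= fixed_tol are flux-fixed (e.g. measured
    uptakes); treating them as equalities keeps every basis direction inside
    the affine hull of the feasible set, which sampling and optimization
    need.  The resulting dof can be smaller than the pure stoichiometric
    dof.
    """
    S = net.stoichiometric_matrix()
    lb, ub = net.bounds()
    n = len(net.reactions)
    rows = [S] if S.size else []
    fixed = np.flatnonzero(ub - lb <= fixed_tol)
    if fixed.size:
        E = np.zeros((fixed.size, n))
        E[np.arange(fixed.size), fixed] = 1.0
        rows.append(E)
    if not rows:
        return NullSpaceBasis(np.eye(n), n)
    A = np.vstack(rows)
    N = linalg.null_space(A, rcond=RANK_TOL)
    return NullSpaceBasis(N, N.shape[1])


def _solve_lp(c, S, lb, ub):
    res = linprog(c, A_eq=S, b_eq=np.zeros(S.shape[0]),
                  bounds=list(zip(lb, ub)), method="highs")
    if res.status == 2:
        raise InfeasibleError("steady-state constraint set is infeasible")
    if not res.success:
        raise RuntimeError(f"LP failed: {res.message}")
    return res


def flux_variability(
    net: AtomMappedNetwork,
    extra_constraints: dict[str, tuple[float, float]] | None = None,
) -> dict[str, tuple[float, float]]:
    """Per-reaction [min, max] flux under S v = 0 and bounds.

    ``extra_constraints`` maps reaction id -> (lower, upper) overrides, e.g.
    measured uptake rates.  A zero-width range flags a reaction whose flux is
    fixed by the constraints alone ("constraint determined").
    """
    S = net.stoichiometric_matrix()
    lb, ub = net.bounds()
    if extra_constraints:
        ids = net.reaction_ids
        for rid, (lo, hi) in extra_constraints.items():
            j = ids.index(rid)
            lb[j], ub[j] = max(lb[j], lo), min(ub[j], hi)
    out = {}
    n = len(net.reactions)
    for j, rid in enumerate(net.reaction_ids):
        c = np.zeros(n)
        c[j] = 1.0
        vmin = _solve_lp(c, S, lb, ub).x[j]
        vmax = _solve_lp(-c, S, lb, ub).x[j]
        out[rid] = (float(min(vmin, vmax)), float(max(vmin, vmax)))
    return out


def find_blocked_reactions(
    net: AtomMappedNetwork, tol: float = 1e-7
) -> set[str]:
    """Reactions that cannot carry flux anywhere in the bounded polytope."""
    fva = flux_variability(net)
    return {rid for rid, (lo, hi) in fva.items()
            if max(abs(lo), abs(hi)) <= tol}
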