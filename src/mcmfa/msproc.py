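"""Turning raw GC-MS mass intensities into corrected mass distributions.

Raw intensities for a fragment (M+0 .. M+6) are normalized to fractions,
corrected for naturally occurring heavy isotopes of the fragment's
non-tracer atoms (H, N, O, Si, S, and derivatization-moiety C) with a
matrix-based probabilistic method, and optionally corrected for carry-over
of unlabeled inoculum biomass.

The correction matrix column for a molecule carrying m tracer labels is the
mass-shift distribution contributed by the non-tracer atoms: a convolution
of per-element binomial/multinomial isotope distributions, truncated to the
observed M+0..M+6 window (so columns sum to at most one).
"""

from __future__ import annotations

import numpy as np

#: natural heavy-isotope probabilities per element: list of (mass shift, p)
#: standard IUPAC isotopic compositions
NATURAL_ABUNDANCES: dict[str, list[tuple[int, float]]] = {
    "C": [(1, 0.0107)],
    "H": [(1, 0.000115)],
    "N": [(1, 0.00364)],
    "O": [(1, 0.00038), (2, 0.00205)],
    "Si": [(1, 0.0468), (2, 0.0310)],
    "S": [(1, 0.0075), (2, 0.0425)],
}

#: GC-MS scan window: M+0 .. M+6
N_MASSES = 7


def normalize_mdv(raw: np.ndarray) -> np.ndarray:
    """Normalize raw intensities by the sum over the observed window."""
    raw = np.asarray(raw, float)
    if (raw < 0).any():
        raise ValueError("negative raw intensities")
    total = raw.sum()
    if total <= 0:
        raise ValueError("all-zero intensity vector")
    return raw / total


def _element_distribution(shifts: list[tuple[int, float]], n_atoms: int,
                          n_masses: int) -> np.ndarray:
    """Mass-shift distribution of n_atoms of one element (multinomial over
    light + heavy isotopes), truncated to n_masses."""
    p_light = 1.0 - sum(p for _, p in shifts)
    single = np.zeros(n_masses)
    single[0] = p_light
    for shift, p in shifts:
        if shift < n_masses:
            single[shift] += p
    out = np.zeros(n_masses)
    out[0] = 1.0
    for _ in range(n_atoms):
        out = np.convolve(out, single)[:n_masses]
    return out


def build_correction_matrix(
    composition: dict[str, int],
    abundances: dict[str, list[tuple[int, float]]] | None = None,
    n_masses: int = N_MASSES,
) -> np.ndarray:
    """Square matrix mapping the true tracer MDV to the observed MDV.

    ``composition`` counts the fragment's non-tracer atoms (the tracked
    carbons are excluded).  Entry (m', m) is the probability that a molecule
    with m tracer labels is observed at shift m'.  With the window truncated,
    columns sum to <= 1.
    """
    abundances = abundances if abundances is not None else NATURAL_ABUNDANCES
    for el, shifts in abundances.items():
        if any(p < 0 for _, p in shifts):
            raise ValueError(f"negative abundance for {el}")
    contamination = np.zeros(n_masses)
    contamination[0] = 1.0
    for el, n in composition.items():
        if n == 0:
            continue
        if el not in abundances:
            raise ValueError(f"no abundance data for element {el!r}")
        contamination = np.convolve(
            contamination,
            _element_distribution(abundances[el], n, n_masses))[:n_masses]
    mat = np.zeros((n_masses, n_masses))
    for m in range(n_masses):
        mat[m:, m] = contamination[: n_masses - m]
    return mat


def correct_natural_abundance(
    observed: np.ndarray,
    matrix: np.ndarray,
    cond_max: float = 1e8,
) -> np.ndarray:
    """Invert the natural-abundance contamination of an observed MDV.

    Solves matrix . x = observed by least squares, clips small negative
    entries, and renormalizes; contaminating an exact MDV and correcting it
    round-trips to ~1e-6.
    """
    observed = np.asarray(observed, float)
    if np.linalg.cond(matrix) > cond_max:
        raise ValueError("correction matrix is ill-conditioned")
    x, *_ = np.linalg.lstsq(matrix, observed, rcond=None)
    x = np.clip(x, 0.0, None)
    total = x.sum()
    if total <= 0:
        raise ValueError("correction produced an empty distribution")
    return x / total


def correct_inoculum_carryover(
    observed: np.ndarray,
    unlabeled_reference: np.ndarray,
    fraction: float,
) -> np.ndarray:
    """Remove the contribution of unlabeled inoculum biomass.

    ``observed = (1 - fraction) * true + fraction * unlabeled_reference``
    is inverted, clipped at zero, and renormalized.
    """
    if not 0 <= fraction < 1:
        raise ValueError("carryover fraction must be in [0, 1)")
    observed = np.asarray(observed, float)
    ref = np.asarray(unlabeled_reference, float)
    x = (observed - fraction * ref) / (1.0 - fraction)
    x = np.clip(x, 0.0, None)
    return x / x.sum()


def process_raw_intensities(
    raw: np.ndarray,
    composition: dict[str, int],
    carryover_fraction: float = 0.0,
    unlabeled_reference: np.ndarray | None = None,
    abundances: dict[str, list[tuple[int, float]]] | None = None,
) -> np.ndarray:
    """Full pipeline: normalize, natural-abundance correct, carryover
    correct."""
    mdv = normalize_mdv(raw)
    mat = build_correction_matrix(composition, abundances, len(mdv))
    mdv = correct_natural_abundance(mdv, mat)
    if carryover_fraction > 0:
        if unlabeled_reference is None:
            raise ValueError("carryover correction needs a reference MDV")
        mdv = correct_inoculum_carryover(mdv, unlabeled_reference,
                                         carryover_fraction)
    return mdv
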