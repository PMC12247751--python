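"""Recovery, reliability, and modulation-structure metrics.

Recovery of a fitted model against a known ground truth is measured by
Pearson correlations over the structurally free entries of each block:
the sparsity mask zeroes 75% of the off-diagonal Wee/Wei entries in both
truth and fit, so including those forced zeros would inflate the
correlation; they are excluded by default.  Pearson r is scale-invariant,
matching the identifiability of W and Gamma up to a common scaling.

Split-half reliability compares models fitted to the two temporal halves
of each subject's data: within-subject correlations (a subject's two
halves) against across-subject correlations (halves of different
subjects), with a Wilcoxon rank-sum test between the two distributions.

The modulation impact between temporally adjacent regimes a -> b is
``W o (Gamma_b - Gamma_a)``: positive entries are connections
strengthened by the transition, negative entries weakened.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations

import numpy as np
from scipy import stats

from .model import ModelParameters, ModulationMatrix, StructuredConnectivity

__all__ = [
    "RecoveryReport",
    "ImpactMatrix",
    "masked_correlation",
    "split_half_reliability",
    "modulation_impact",
    "gamma_value_summary",
]


def _pearson(a: np.ndarray, b: np.ndarray) -> float:
    a = np.asarray(a, dtype=float).ravel()
    b = np.asarray(b, dtype=float).ravel()
    if a.size != b.size:
        raise ValueError("vectors must have equal length")
    if a.size < 2 or np.std(a) == 0 or np.std(b) == 0:
        raise ValueError("correlation undefined for zero-variance input")
    return float(np.corrcoef(a, b)[0, 1])


@dataclass
class RecoveryReport:
    """Pearson correlations between true and fitted parameters."""

    r_full_W: float
    r_Wee: float
    r_Wei: float
    r_gamma_ee: list  # per regime
    r_gamma_ei: list  # per regime
    mask_used: np.ndarray | None = None

    def as_dict(self) -> dict:
        return {
            "r_full_W": self.r_full_W,
            "r_Wee": self.r_Wee,
            "r_Wei": self.r_Wei,
            "r_gamma_ee": list(self.r_gamma_ee),
            "r_gamma_ei": list(self.r_gamma_ei),
        }


@dataclass
class ImpactMatrix:
    value: np.ndarray
    from_regime: int
    to_regime: int

    def postsynaptic(self) -> np.ndarray:
        """Row-wise (per target population) mean impact."""
        return self.value.mean(axis=1)


def _effective_masks(W: StructuredConnectivity, include_masked: bool):
    """Boolean selections of the free entries per block (diagonals kept)."""
    if include_masked:
        m_ee = np.ones_like(W.mask_ee, dtype=bool)
        m_ei = np.ones_like(W.mask_ei, dtype=bool)
    else:
        m_ee = W.mask_ee.astype(bool)
        m_ei = W.mask_ei.astype(bool)
    return m_ee, m_ei


def masked_correlation(true_params: ModelParameters,
                       fitted_params: ModelParameters,
                       include_masked: bool = False) -> RecoveryReport:
    """Blockwise Pearson correlation between true and fitted parameters.

    The full-W correlation is computed over all structurally free entries
    (mask-surviving Wee/Wei entries, block diagonals, and the Wie/Wii
    diagonals); the Gamma correlations are computed per regime over the
    effective EE and EI sub-blocks, through which the sparsity mask
    propagates via the Hadamard product.  ``include_masked=True`` instead
    correlates over all block entries, including the shared forced zeros.
    """
    tw, fw = true_params.W, fitted_params.W
    if (tw.n_exc, tw.n_inh) != (fw.n_exc, fw.n_inh):
        raise ValueError("shape mismatch between true and fitted models")
    if true_params.m != fitted_params.m:
        raise ValueError("regime count mismatch")
    m_ee, m_ei = _effective_masks(tw, include_masked)
    r_ee = _pearson(tw.Wee[m_ee], fw.Wee[m_ee])
    r_ei = _pearson(tw.Wei[m_ei], fw.Wei[m_ei])
    full_true = np.concatenate([
        tw.Wee[m_ee], tw.Wei[m_ei], np.diag(tw.Wie), np.diag(tw.Wii)])
    full_fit = np.concatenate([
        fw.Wee[m_ee], fw.Wei[m_ei], np.diag(fw.Wie), np.diag(fw.Wii)])
    r_full = _pearson(full_true, full_fit)
    ne = tw.n_exc
    r_gee, r_gei = [], []
    for gt, gf in zip(true_params.gammas, fitted_params.gammas):
        Gt, Gf = gt.dense(), gf.dense()
        for blk_t, blk_f, out in (
            (Gt[:ne, :ne][m_ee], Gf[:ne, :ne][m_ee], r_gee),
            (Gt[ne:, :ne][m_ei], Gf[ne:, :ne][m_ei], r_gei),
        ):
            # a pinned/constant modulation block has no variance to correlate
            if np.std(blk_t) == 0 or np.std(blk_f) == 0:
                out.append(np.nan)
            else:
                out.append(_pearson(blk_t, blk_f))
    full_mask = np.zeros((tw.n, tw.n), dtype=bool)
    full_mask[:ne, :ne] = m_ee
    full_mask[ne:, :ne] = m_ei
    full_mask[:ne, ne:] = np.eye(ne, tw.n_inh, dtype=bool)
    full_mask[ne:, ne:] = np.eye(tw.n_inh, dtype=bool)
    return RecoveryReport(r_full, r_ee, r_ei, r_gee, r_gei, full_mask)


def _half_vector(item, mask: np.ndarray | None) -> np.ndarray:
    """Flatten a half-fit into a comparison vector.

    ``item`` is a ModelParameters, a StructuredConnectivity, or a plain
    matrix; ``mask`` optionally selects entries."""
    if isinstance(item, ModelParameters):
        item = item.W
    if isinstance(item, StructuredConnectivity):
        item = item.assemble()
    arr = np.asarray(item, dtype=float)
    if mask is not None:
        return arr[np.asarray(mask, dtype=bool)]
    return arr.ravel()


def split_half_reliability(fits_by_subject, mask: np.ndarray | None = None,
                           alternative: str = "two-sided"):
    """Within- vs across-subject correlation of split-half fitted W.

    ``fits_by_subject`` maps subject id -> (half1, half2), each half a
    ModelParameters, StructuredConnectivity, or matrix.  Returns
    ``(within_r, across_r, p_value)``: within_r has one entry per subject
    (its two halves correlated); across_r has 4 entries per unordered
    subject pair (every half of one subject against every half of the
    other); the p-value is a Wilcoxon rank-sum (Mann-Whitney U) test
    comparing the two distributions.
    """
    subjects = list(fits_by_subject)
    if len(subjects) < 2:
        raise ValueError("need at least 2 subjects")
    halves = {}
    for s in subjects:
        pair = fits_by_subject[s]
        if len(pair) != 2:
            raise ValueError(f"subject {s!r} must have exactly 2 half-fits")
        halves[s] = [_half_vector(pair[0], mask), _half_vector(pair[1], mask)]
    within = np.array([_pearson(halves[s][0], halves[s][1]) for s in subjects])
    across = np.array([
        _pearson(halves[s1][h1], halves[s2][h2])
        for s1, s2 in combinations(subjects, 2)
        for h1 in (0, 1) for h2 in (0, 1)
    ])
    res = stats.mannwhitneyu(within, across, alternative=alternative)
    return within, across, float(res.pvalue)


def modulation_impact(W, gamma_a, gamma_b) -> ImpactMatrix:
    """Signed change in effective connectivity between two regimes,
    ``W o (Gamma_b - Gamma_a)``."""
    if isinstance(W, StructuredConnectivity):
        W = W.assemble()
    W = np.asarray(W, dtype=float)

    def _dense(g):
        return g.dense() if isinstance(g, ModulationMatrix) else np.asarray(g, dtype=float)

    Ga, Gb = _dense(gamma_a), _dense(gamma_b)
    if Ga.shape != W.shape or Gb.shape != W.shape:
        raise ValueError("modulation shapes must match W")
    a_idx = gamma_a.regime_index if isinstance(gamma_a, ModulationMatrix) else 0
    b_idx = gamma_b.regime_index if isinstance(gamma_b, ModulationMatrix) else 0
    return ImpactMatrix(W * (Gb - Ga), a_idx, b_idx)


def gamma_value_summary(gammas, mask_ee: np.ndarray | None = None,
                        mask_ei: np.ndarray | None = None,
                        n_exc: int | None = None) -> list:
    """Per-regime distribution summary of modulation values.

    Counts are over the effective entries: when masks are given, only
    mask-surviving EE and EI sub-block entries are scanned (those are the
    entries that survive the Hadamard product with the sparse W);
    otherwise all entries.  Entries exactly equal to 1 count as "not
    greater than 1" (strict inequality).  Returns one dict per regime with
    counts, fractions, and quartiles.
    """
    out = []
    for g in gammas:
        G = g.dense() if isinstance(g, ModulationMatrix) else np.asarray(g, dtype=float)
        if mask_ee is not None and n_exc is not None:
            vals = [G[:n_exc, :n_exc][np.asarray(mask_ee, dtype=bool)]]
            if mask_ei is not None:
                vals.append(G[n_exc:, :n_exc][np.asarray(mask_ei, dtype=bool)])
            vals = np.concatenate(vals)
        else:
            vals = G.ravel()
        n = vals.size
        n_gt1 = int(np.sum(vals > 1.0))
        n_unit = int(np.sum((vals >= 0.0) & (vals < 1.0)))
        q1, med, q3 = np.percentile(vals, [25, 50, 75])
        out.append({
            "regime": getattr(g, "regime_index", None),
            "n_entries": n,
            "n_greater_than_1": n_gt1,
            "frac_greater_than_1": n_gt1 / n,
            "n_in_unit_interval": n_unit,
            "frac_in_unit_interval": n_unit / n,
            "q1": float(q1), "median": float(med), "q3": float(q3),
        })
    return out
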