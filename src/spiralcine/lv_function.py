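"""Left-ventricular functional parameters and method-agreement statistics.

Volumes follow Simpson's rule over contiguous short-axis slices: the blood
pool is the endocardial voxel count times the voxel volume, myocardium the
epi-minus-endo count.  End-diastole/end-systole are the blood-volume
argmax/argmin over cardiac phases (earliest phase on ties).  Mass uses the
conventional myocardial density of 1.05 g/mL.

Agreement between two measurement methods uses Bland-Altman bias and
mean +/- 1.96*SD limits with a one-sample t-test of the bias against zero;
group comparisons use Welch's unequal-variance t-test; paired ordinal scores
use the Wilcoxon signed-rank test with exact sign-permutation p-values for
n <= 25 (zeros discarded, mid-ranks for ties) and a tie-corrected normal
approximation beyond.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from .phantom import MYOCARDIAL_DENSITY_G_PER_ML


class AnalysisError(ValueError):
    pass


@dataclass(frozen=True)
class SegmentationMasks:
    """Binary endo/epi masks per phase, (n_phases, nz, ny, nx), voxel in mm."""

    endo: np.ndarray
    epi: np.ndarray
    voxel_mm: tuple

    def __post_init__(self) -> None:
        if self.endo.shape != self.epi.shape:
            raise AnalysisError("endo and epi masks must share a grid")
        if np.any(self.endo & ~self.epi):
            raise AnalysisError("endocardial mask must lie inside epicardial")


@dataclass(frozen=True)
class FunctionReport:
    """EDV/ESV/SV/EF/EDM with the phase indices they came from."""

    edv_ml: float
    esv_ml: float
    sv_ml: float
    ef_pct: float
    edm_g: float
    ed_phase: int
    es_phase: int

    def __post_init__(self) -> None:
        if not (0 <= self.esv_ml <= self.edv_ml):
            raise AnalysisError("require 0 <= ESV <= EDV")

    def as_dict(self) -> dict:
        return {k: getattr(self, k) for k in
                ("edv_ml", "esv_ml", "sv_ml", "ef_pct", "edm_g",
                 "ed_phase", "es_phase")}


def compute_volumes(masks: SegmentationMasks, phase: int) -> tuple:
    """(blood, myocardium) volumes in mL at one cardiac phase."""
    voxel_ml = float(np.prod(masks.voxel_mm)) / 1000.0
    endo = masks.endo[phase]
    myo = masks.epi[phase] & ~masks.endo[phase]
    return endo.sum() * voxel_ml, myo.sum() * voxel_ml


def select_ed_es(blood_volumes: np.ndarray) -> tuple[int, int]:
    """(ed_phase, es_phase) = argmax/argmin blood volume, earliest on ties."""
    v = np.asarray(blood_volumes)
    if v.size < 2:
        raise AnalysisError("need >= 2 phases to pick ED and ES")
    return int(np.argmax(v)), int(np.argmin(v))


def functional_report(masks: SegmentationMasks,
                      density_g_per_ml: float = MYOCARDIAL_DENSITY_G_PER_ML
                      ) -> FunctionReport:
    """Functional parameters from per-phase segmentation masks."""
    n_phases = masks.endo.shape[0]
    vols = np.array([compute_volumes(masks, p) for p in range(n_phases)])
    return report_from_volumes(vols[:, 0], vols[:, 1], density_g_per_ml)


def report_from_volumes(blood_ml: np.ndarray, myo_ml: np.ndarray,
                        density_g_per_ml: float = MYOCARDIAL_DENSITY_G_PER_ML
                        ) -> FunctionReport:
    """Functional parameters from per-phase blood/myocardial volumes."""
    ed, es = select_ed_es(blood_ml)
    edv, esv = float(blood_ml[ed]), float(blood_ml[es])
    if edv == 0:
        raise AnalysisError("EDV = 0: ejection fraction undefined")
    return FunctionReport(
        edv_ml=edv, esv_ml=esv, sv_ml=edv - esv,
        ef_pct=100.0 * (edv - esv) / edv,
        edm_g=float(myo_ml[ed]) * density_g_per_ml,
        ed_phase=ed, es_phase=es)


def segment_blood_pool(volumes: np.ndarray, roi: tuple | None = None,
                       threshold_fraction: float = 0.675) -> np.ndarray:
    """Threshold segmentation of the blood pool on reconstructed magnitude
    volumes (n_phases, nz, ny, nx).

    The threshold is `threshold_fraction` of the robust maximum (99.5th
    percentile, an estimate of the blood-pool level) inside the region of
    interest, computed at the first phase and held fixed across phases so ED
    and ES are segmented consistently.  The default fraction is the
    full-width-at-half-maximum boundary criterion: the midpoint between the
    blood level and a myocardium at 0.35 of blood, (1 + 0.35)/2, which under
    a symmetric point-spread function places the boundary at the true edge.
    roi = (zslice, yslice, xslice) restricts both the reference level and
    the mask; default is the full grid.
    """
    volumes = np.asarray(volumes)
    if roi is None:
        roi = (slice(None),) * 3
    ref = np.percentile(volumes[(0,) + tuple(roi)], 99.5)
    thr = threshold_fraction * ref
    mask = np.zeros(volumes.shape, bool)
    sub = volumes[(slice(None),) + tuple(roi)] >= thr
    mask[(slice(None),) + tuple(roi)] = sub
    return mask


# -- agreement statistics -----------------------------------------------------

@dataclass(frozen=True)
class BlandAltman:
    """Bias, SD and mean +/- 1.96*SD limits of paired differences A - B."""

    bias: float
    sd: float
    lower: float
    upper: float
    bias_p: float
    n: int

    def summary(self) -> str:
        return (f"Bland-Altman (n={self.n}): bias {self.bias:.2f}, "
                f"SD {self.sd:.2f}, limits [{self.lower:.2f}, "
                f"{self.upper:.2f}], bias-vs-0 p = {self.bias_p:.3g}")


def limits_of_agreement(bias: float, sd: float) -> tuple[float, float]:
    """(lower, upper) = bias -/+ 1.96 * SD."""
    return bias - 1.96 * sd, bias + 1.96 * sd


def bland_altman(a, b) -> BlandAltman:
    """Bland-Altman agreement of paired measurements a and b (a - b)."""
    a, b = np.asarray(a, float), np.asarray(b, float)
    if a.shape != b.shape or a.size < 2:
        raise AnalysisError("need >= 2 pairs of equal length")
    d = a - b
    bias = float(d.mean())
    sd = float(d.std(ddof=1))
    lo, hi = limits_of_agreement(bias, sd)
    if sd == 0:
        p = 1.0 if bias == 0 else 0.0
    else:
        p = float(stats.ttest_1samp(d, 0.0).pvalue)
    return BlandAltman(bias=bias, sd=sd, lower=lo, upper=hi, bias_p=p,
                       n=d.size)


def plot_bland_altman(a, b, ax=None, label: str = ""):
    """Bland-Altman plot: differences vs means with the bias (solid) and
    the 1.96*SD limits of agreement (dashed).  Returns the axes."""
    import matplotlib.pyplot as plt

    a, b = np.asarray(a, float), np.asarray(b, float)
    ba = bland_altman(a, b)
    if ax is None:
        _, ax = plt.subplots()
    ax.scatter((a + b) / 2.0, a - b, color="k", s=18)
    ax.axhline(ba.bias, color="gray")
    for y in (ba.lower, ba.upper):
        ax.axhline(y, color="gray", linestyle="--")
    ax.set_xlabel(f"mean of methods {label}".strip())
    ax.set_ylabel(f"difference {label}".strip())
    return ax


@dataclass(frozen=True)
class WelchResult:
    t: float
    df: float
    p: float


def welch_t_test(a, b) -> WelchResult:
    """Welch's unequal-variance t-test with Welch-Satterthwaite df."""
    a, b = np.asarray(a, float), np.asarray(b, float)
    if a.size < 2 or b.size < 2:
        raise AnalysisError("both samples need >= 2 values")
    va, vb = a.var(ddof=1), b.var(ddof=1)
    if va == 0 and vb == 0:
        raise AnalysisError("zero variance in both samples: t undefined")
    res = stats.ttest_ind(a, b, equal_var=False)
    sa, sb = va / a.size, vb / b.size
    df = (sa + sb) ** 2 / (sa ** 2 / (a.size - 1) + sb ** 2 / (b.size - 1))
    return WelchResult(t=float(res.statistic), df=float(df),
                       p=float(res.pvalue))


@dataclass(frozen=True)
class WilcoxonResult:
    w: float           # sum of ranks of positive differences
    p: float
    n: int             # nonzero differences used
    exact: bool


def _signed_rank_distribution(ranks2: np.ndarray) -> tuple:
    """Exact null distribution of 2*W over all sign assignments of the given
    (doubled, integer) ranks, via dynamic programming.  Returns (support
    counts array c, total), where c[s] = #assignments with 2*W = s."""
    total = int(ranks2.sum())
    counts = np.zeros(total + 1, dtype=float)
    counts[0] = 1.0
    for r in ranks2:
        nxt = counts.copy()
        nxt[r:] += counts[: total + 1 - r]
        counts = nxt
    return counts, 2.0 ** len(ranks2)


def wilcoxon_signed_rank(diffs, exact_max_n: int = 25) -> WilcoxonResult:
    """Wilcoxon signed-rank test of paired differences against median 0.

    Zeros are discarded (classical handling); tied absolute differences get
    mid-ranks.  W is the sum of positive-difference ranks.  For n <=
    `exact_max_n` the two-sided p is exact over all 2^n sign assignments
    (mid-ranks included, so ties are handled exactly under the permutation
    null); otherwise the normal approximation with tie correction is used.
    """
    d = np.asarray(diffs, float)
    d = d[d != 0]
    n = d.size
    if n == 0:
        raise AnalysisError("all differences are zero: test undefined")
    ranks = stats.rankdata(np.abs(d))
    w_pos = float(ranks[d > 0].sum())
    mu = n * (n + 1) / 4.0
    if n <= exact_max_n:
        ranks2 = np.rint(2.0 * ranks).astype(int)
        counts, total = _signed_rank_distribution(ranks2)
        s = int(round(2.0 * w_pos))
        lo = counts[: s + 1].sum() / total          # P(2W <= s)
        hi = counts[s:].sum() / total               # P(2W >= s)
        p = min(1.0, 2.0 * min(lo, hi))
        return WilcoxonResult(w=w_pos, p=p, n=n, exact=True)
    tie_term = ((np.bincount(np.rint(2 * ranks).astype(int)) ** 3).sum()
                - np.bincount(np.rint(2 * ranks).astype(int)).sum()) / 48.0
    var = n * (n + 1) * (2 * n + 1) / 24.0 - tie_term
    z = (w_pos - mu) / np.sqrt(var)
    p = float(2.0 * stats.norm.sf(abs(z)))
    return WilcoxonResult(w=w_pos, p=min(p, 1.0), n=n, exact=False)
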