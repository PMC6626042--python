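"""Cargo-transfer, protease-accessibility and population-mixing statistics.

Covers the measurement side of outer-membrane exchange: donor/recipient
relative fluorescence over time (ratio normalization cancels acquisition
photobleaching), proteinase-K accessibility ratios F_PK/F_0 with a two-sample
t-test between groups, junction colocalization summaries, and a
population-level homogenization index.

The homogenization index H and the junction colocalization summary are
package-defined conveniences (peak offset, Pearson correlation, H from
per-cell channel balances); they quantify behaviours that are otherwise
assessed visually.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy import stats

from .profiles import Junction

__all__ = [
    "TransferSeries",
    "AccessibilityResult",
    "ColocSummary",
    "MixingSummary",
    "transfer_fraction",
    "pk_accessibility",
    "junction_coloc",
    "homogenization_index",
]


# --------------------------------------------------------------------------
# Donor/recipient transfer fractions
# --------------------------------------------------------------------------


@dataclass
class TransferSeries:
    """Donor/recipient fluorescence and their relative fractions over time."""

    t: np.ndarray
    f_donor: np.ndarray
    f_recipient: np.ndarray
    frac_donor: np.ndarray
    frac_recipient: np.ndarray


def transfer_fraction(f_donor: np.ndarray, f_recipient: np.ndarray,
                      times: np.ndarray | None = None) -> TransferSeries:
    """Relative donor/recipient fluorescence at each time point.

    f_d = F_d/(F_d + F_r) and f_r = F_r/(F_d + F_r); any common per-frame
    acquisition-loss factor cancels, and f_d + f_r = 1 exactly.
    """
    fd = np.asarray(f_donor, dtype=float)
    fr = np.asarray(f_recipient, dtype=float)
    if fd.shape != fr.shape or fd.ndim != 1:
        raise ValueError("donor and recipient series must be equal-length vectors")
    if np.any(fd < 0) or np.any(fr < 0):
        raise ValueError("fluorescence values must be >= 0")
    tot = fd + fr
    if np.any(tot == 0):
        bad = int(np.flatnonzero(tot == 0)[0])
        raise ValueError(f"F_donor + F_recipient is zero at time point {bad}")
    t = np.arange(len(fd), dtype=float) if times is None else np.asarray(times, float)
    return TransferSeries(t=t, f_donor=fd, f_recipient=fr,
                          frac_donor=fd / tot, frac_recipient=fr / tot)


# --------------------------------------------------------------------------
# Proteinase-K accessibility
# --------------------------------------------------------------------------


@dataclass
class AccessibilityResult:
    """Per-cell F_PK/F_0 ratios with group summaries and t-tests.

    ``tests`` maps (group_a, group_b) to (t statistic, two-tailed p-value);
    it is empty (with ``notice`` set) when only one group is present.
    """

    ratios: np.ndarray
    groups: np.ndarray
    group_means: dict[str, float]
    group_sds: dict[str, float]
    group_ns: dict[str, int]
    tests: dict[tuple[str, str], tuple[float, float]] = field(default_factory=dict)
    notice: str | None = None
    welch: bool = False


def pk_accessibility(before: np.ndarray, after: np.ndarray,
                     groups: Sequence[str], welch: bool = False) -> AccessibilityResult:
    """Quantify surface exposure from paired per-cell fluorescence.

    ``before`` (F_0) and ``after`` (F_PK) are same-cell measurements; the
    per-cell ratio F_PK/F_0 drops toward 0 for surface-exposed reporters and
    stays near 1 for protected ones.  Groups are compared with an unpaired
    two-tailed t-test (pooled variance by default; ``welch`` switches to the
    unequal-variance form).
    """
    f0 = np.asarray(before, dtype=float)
    fpk = np.asarray(after, dtype=float)
    groups = np.asarray(groups)
    if not (len(f0) == len(fpk) == len(groups)):
        raise ValueError("before, after and groups must have equal length")
    if np.any(f0 == 0):
        bad = int(np.flatnonzero(f0 == 0)[0])
        raise ValueError(f"F_0 is zero for cell {bad}: ratio undefined")
    if np.any(f0 < 0) or np.any(fpk < 0):
        raise ValueError("fluorescence values must be >= 0")
    ratios = fpk / f0

    labels = list(dict.fromkeys(groups.tolist()))  # stable unique
    means = {g: float(ratios[groups == g].mean()) for g in labels}
    sds = {g: float(ratios[groups == g].std(ddof=1)) if np.sum(groups == g) > 1 else 0.0
           for g in labels}
    ns = {g: int(np.sum(groups == g)) for g in labels}

    tests: dict[tuple[str, str], tuple[float, float]] = {}
    notice = None
    if len(labels) < 2:
        notice = "single group: summary statistics only, no significance test performed"
    else:
        for i, ga in enumerate(labels):
            for gb in labels[i + 1:]:
                res = stats.ttest_ind(ratios[groups == ga], ratios[groups == gb],
                                      equal_var=not welch)
                tests[(ga, gb)] = (float(res.statistic), float(res.pvalue))
    return AccessibilityResult(ratios=ratios, groups=groups, group_means=means,
                               group_sds=sds, group_ns=ns, tests=tests,
                               notice=notice, welch=welch)


# --------------------------------------------------------------------------
# Junction colocalization
# --------------------------------------------------------------------------


@dataclass
class ColocSummary:
    """Two-channel overlap at one junction (package-defined summary)."""

    peak_offset_um: float
    pearson_r: float
    r_defined: bool
    channels: tuple[str, str]
    note: str = "package-defined colocalization summary (peak offset + Pearson r)"


def junction_coloc(junction: Junction) -> ColocSummary:
    """Peak-position offset and Pearson correlation of a dual-channel junction.

    Profiles are peak-normalized internally (correlation and argmax are both
    scale-free, so this only guards against numeric extremes).  A constant
    profile in either channel makes the correlation undefined, which is
    reported via ``r_defined=False``.
    """
    if len(junction.channels) != 2:
        raise ValueError("junction colocalization needs exactly two channels")
    ch_a, ch_b = junction.channels
    pa, pb = junction.profiles[ch_a], junction.profiles[ch_b]
    offset = float(pa.s[np.argmax(pa.intensity)] - pb.s[np.argmax(pb.intensity)])
    ya, yb = pa.intensity, pb.intensity
    if np.ptp(ya) == 0 or np.ptp(yb) == 0:
        return ColocSummary(peak_offset_um=offset, pearson_r=float("nan"),
                            r_defined=False, channels=(ch_a, ch_b))
    r = float(stats.pearsonr(ya, yb).statistic)
    return ColocSummary(peak_offset_um=offset, pearson_r=r, r_defined=True,
                        channels=(ch_a, ch_b))


# --------------------------------------------------------------------------
# Population homogenization
# --------------------------------------------------------------------------


@dataclass
class MixingSummary:
    """Population-level label mixing (package-defined index).

    H = 1 - 2 * mean|b_i - 0.5| with b_i = ch1/(ch1+ch2) per cell: 0 for a
    perfectly bimodal population (every cell purely one label), 1 when every
    cell carries an even channel balance.
    """

    balances: np.ndarray
    h: float
    n_cells: int
    n_excluded: int = 0
    time_label: str | None = None
    note: str = "package-defined homogenization index"


def homogenization_index(ch1: np.ndarray, ch2: np.ndarray,
                         time_label: str | None = None) -> MixingSummary:
    """Homogenization index from per-cell two-channel mean intensities.

    Cells with zero total signal are excluded with a warning.  The index is
    invariant to swapping the channels and to global intensity rescaling.
    """
    a = np.asarray(ch1, dtype=float)
    b = np.asarray(ch2, dtype=float)
    if a.shape != b.shape or a.ndim != 1:
        raise ValueError("channel vectors must be equal-length 1-D arrays")
    if len(a) < 2:
        raise ValueError("need >= 2 cells")
    if np.any(a < 0) or np.any(b < 0):
        raise ValueError("intensities must be >= 0")
    tot = a + b
    keep = tot > 0
    n_excl = int(np.sum(~keep))
    if n_excl:
        warnings.warn(f"excluded {n_excl} cell(s) with zero total signal", stacklevel=2)
    if np.sum(keep) < 2:
        raise ValueError("fewer than 2 cells with signal")
    bal = a[keep] / tot[keep]
    h = float(np.clip(1.0 - 2.0 * np.mean(np.abs(bal - 0.5)), 0.0, 1.0))
    return MixingSummary(balances=bal, h=h, n_cells=int(np.sum(keep)),
                         n_excluded=n_excl, time_label=time_label)
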