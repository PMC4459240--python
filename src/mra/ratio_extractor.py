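"""LDA ratio extractor: best-discriminating body ratios for two groups.

The extractor searches all p(p−1)/2 unordered character pairs {a, b} for the
log-ratio ln x_a − ln x_b that best separates two groups, ranked by the
*standard distance*

    D = |v · (m₁ − m₂)| / sqrt(v · S_pooled · v)

(group-mean difference of the projection over its pooled within-group SD,
pooled covariance with n₁ + n₂ − 2 denominator).  The second-best ratio is
the pair that, jointly with the first, maximizes the two-dimensional
Mahalanobis standard distance — it complements the first ratio rather than
being the second-largest marginal D.  The measure

    δ = D_size / D_ratio

compares how well size separates the groups relative to the extracted ratio
(D_size is the standard distance of isosize); δ near 0 means the groups
differ in shape, not merely in size.
"""

from __future__ import annotations

import io
import itertools
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .measurement_data import MeasurementTable

__all__ = [
    "GroupComparison",
    "ExtractedRatio",
    "RatioExtractionResult",
    "standard_distance",
    "isosize_distance",
    "delta",
    "extract_best_ratios",
    "ratio_ranges",
    "table2_report",
]


@dataclass
class GroupComparison:
    """Two disjoint specimen groups to be separated.

    Each label may denote a union of OTUs (e.g. ``"cala + corn"``); members
    are row indices into the measurement table.
    """

    label_1: str
    label_2: str
    members_1: list
    members_2: list

    def __post_init__(self) -> None:
        s1, s2 = set(self.members_1), set(self.members_2)
        if s1 & s2:
            raise ValueError("groups overlap")
        if len(s1) < 3 or len(s2) < 3:
            raise ValueError("each group needs at least 3 specimens")

    @classmethod
    def from_table(cls, table: MeasurementTable, groups_1, groups_2,
                   label_1: str | None = None,
                   label_2: str | None = None) -> "GroupComparison":
        """Build a comparison from OTU labels (each side a label or list)."""
        g1 = [groups_1] if isinstance(groups_1, str) else list(groups_1)
        g2 = [groups_2] if isinstance(groups_2, str) else list(groups_2)
        m1 = [sid for sid, g in table.group.items() if g in g1]
        m2 = [sid for sid, g in table.group.items() if g in g2]
        return cls(label_1 or " + ".join(g1), label_2 or " + ".join(g2), m1, m2)


@dataclass
class ExtractedRatio:
    """One extracted ratio with its separation statistics.

    ``overlap_flag`` is True when the two groups' observed ratio ranges
    overlap at all; ``starred`` is True when the overlap is very small
    (≤ 5% of the union length), making the ratio usable as a diagnostic
    character in a key.
    """

    numerator: str
    denominator: str
    D: float
    delta: float
    range_1: tuple[float, float]
    range_2: tuple[float, float]
    overlap_flag: bool
    starred: bool = False

    @property
    def name(self) -> str:
        return f"{self.numerator} : {self.denominator}"


@dataclass
class RatioExtractionResult:
    comparison: GroupComparison
    ratios: list[ExtractedRatio]
    D_size: float
    low_separation: bool = False
    skipped_pairs: list[tuple[str, str]] = field(default_factory=list)


# ----------------------------------------------------------------------


def _log_matrix(table: MeasurementTable, members) -> np.ndarray:
    sub = table.values.loc[members].to_numpy(dtype=float)
    if np.isnan(sub).any():
        raise ValueError("missing values present; impute first")
    return np.log(sub)


def _pooled_stats(L1: np.ndarray, L2: np.ndarray):
    n1, n2 = len(L1), len(L2)
    m1, m2 = L1.mean(axis=0), L2.mean(axis=0)
    S = ((L1 - m1).T @ (L1 - m1) + (L2 - m2).T @ (L2 - m2)) / (n1 + n2 - 2)
    return m1, m2, S


def standard_distance(direction: np.ndarray, table: MeasurementTable,
                      comparison: GroupComparison) -> float:
    """Standard distance D of the projection onto *direction* in log space."""
    v = np.asarray(direction, dtype=float)
    L1 = _log_matrix(table, comparison.members_1)
    L2 = _log_matrix(table, comparison.members_2)
    m1, m2, S = _pooled_stats(L1, L2)
    denom = float(v @ S @ v)
    if denom <= 0:
        raise ValueError("degenerate direction: zero pooled variance")
    return float(abs(v @ (m1 - m2)) / np.sqrt(denom))


def isosize_distance(table: MeasurementTable,
                     comparison: GroupComparison) -> float:
    """Standard distance of isosize (mean log-measurement) between groups."""
    L1 = _log_matrix(table, comparison.members_1).mean(axis=1)
    L2 = _log_matrix(table, comparison.members_2).mean(axis=1)
    n1, n2 = len(L1), len(L2)
    var = (np.sum((L1 - L1.mean()) ** 2) + np.sum((L2 - L2.mean()) ** 2)) / (n1 + n2 - 2)
    diff = abs(L1.mean() - L2.mean())
    # constant isosize up to round-off: both spread and mean difference at
    # machine scale relative to the isosize magnitude
    scale = max(1.0, abs(L1.mean()), abs(L2.mean()))
    if np.sqrt(var) < 1e-12 * scale:
        return 0.0 if diff < 1e-12 * scale else float("inf")
    return float(diff / np.sqrt(var))


def delta(ratio_direction: np.ndarray, comparison: GroupComparison,
          table: MeasurementTable) -> float:
    """δ = D_size / D_ratio for the given log-ratio direction."""
    d_ratio = standard_distance(ratio_direction, table, comparison)
    if d_ratio == 0:
        raise ValueError("D of the ratio is zero; delta undefined")
    return isosize_distance(table, comparison) / d_ratio


# ----------------------------------------------------------------------


def ratio_ranges(table: MeasurementTable, group, numerator: str,
                 denominator: str) -> tuple[float, float]:
    """Observed min–max of raw ratio x_num / x_den within *group*.

    Specimens with an imputed (or missing) value in either character are
    excluded: imputed values can produce outlying ratios.  *group* may be a
    single OTU label or a list of labels.
    """
    labels = [group] if isinstance(group, str) else list(group)
    in_group = table.group.isin(labels)
    ok = (in_group
          & ~table.imputed_mask[numerator] & ~table.imputed_mask[denominator]
          & ~table.missing_mask[numerator] & ~table.missing_mask[denominator])
    if not ok.any():
        raise ValueError(
            f"no specimen in {labels} with both {numerator} and "
            f"{denominator} measured (non-imputed)")
    r = table.values.loc[ok, numerator] / table.values.loc[ok, denominator]
    return float(r.min()), float(r.max())


def _ranges_for_members(table: MeasurementTable, members, num: str,
                        den: str) -> tuple[float, float] | None:
    ok_mask = (~table.imputed_mask[num] & ~table.imputed_mask[den]
               & ~table.missing_mask[num] & ~table.missing_mask[den])
    members_ok = [m for m in members if bool(ok_mask.loc[m])]
    if not members_ok:
        return None
    r = table.values.loc[members_ok, num] / table.values.loc[members_ok, den]
    return float(r.min()), float(r.max())


def _overlap_small(r1: tuple[float, float], r2: tuple[float, float],
                   frac: float = 0.05) -> bool:
    """True when the two ranges have very little or no overlap
    (overlap length ≤ *frac* of the union length)."""
    lo = max(r1[0], r2[0])
    hi = min(r1[1], r2[1])
    overlap = max(0.0, hi - lo)
    union = max(r1[1], r2[1]) - min(r1[0], r2[0])
    if union == 0:
        return False
    return overlap <= frac * union


def extract_best_ratios(table: MeasurementTable, comparison: GroupComparison,
                        n_ratios: int = 2) -> RatioExtractionResult:
    """Exhaustively search character pairs for the best separating ratios.

    Ratio 1 maximizes the marginal standard distance D over all unordered
    pairs; each further ratio maximizes the joint Mahalanobis standard
    distance together with the ratios already chosen.  Numerator and
    denominator are oriented so the pooled geometric-mean ratio is ≥ 1; ties
    break lexicographically by abbreviation pair.  Per-group raw-ratio ranges
    use non-imputed specimens only.
    """
    cols = table.columns
    p = len(cols)
    if n_ratios > p - 1:
        raise ValueError(f"n_ratios={n_ratios} exceeds p-1={p - 1}")
    L1 = _log_matrix(table, comparison.members_1)
    L2 = _log_matrix(table, comparison.members_2)
    m1, m2, S = _pooled_stats(L1, L2)
    dm = m1 - m2
    pooled_mean = np.concatenate([L1, L2]).mean(axis=0)

    pairs = list(itertools.combinations(range(p), 2))
    # marginal D of every pair, vectorized via the pooled covariance
    skipped: list[tuple[str, str]] = []
    marg = {}
    for a, b in pairs:
        var = S[a, a] + S[b, b] - 2 * S[a, b]
        if var <= 0:
            skipped.append((cols[a], cols[b]))
            continue
        marg[(a, b)] = abs(dm[a] - dm[b]) / np.sqrt(var)
    if not marg:
        raise ValueError("all candidate pairs degenerate")

    def pair_key(ab):
        return (-marg[ab], cols[ab[0]], cols[ab[1]])

    chosen: list[tuple[int, int]] = [min(marg, key=pair_key)]
    scores = [marg[chosen[0]]]

    while len(chosen) < n_ratios:
        # contrast matrix of already-chosen ratios
        best = None
        for ab in sorted(marg, key=lambda ab: (cols[ab[0]], cols[ab[1]])):
            if ab in chosen:
                continue
            cand = chosen + [ab]
            V = np.zeros((len(cand), p))
            for r, (a, b) in enumerate(cand):
                V[r, a], V[r, b] = 1.0, -1.0
            Sj = V @ S @ V.T
            dj = V @ dm
            try:
                md = float(np.sqrt(dj @ np.linalg.solve(Sj, dj)))
            except np.linalg.LinAlgError:
                skipped.append((cols[ab[0]], cols[ab[1]]))
                continue
            if not np.isfinite(md):
                skipped.append((cols[ab[0]], cols[ab[1]]))
                continue
            if best is None or md > best[0] + 1e-12:
                best = (md, ab)
        if best is None:
            warnings.warn("no further non-degenerate ratio available",
                          stacklevel=2)
            break
        chosen.append(best[1])
        scores.append(best[0])

    d_size = isosize_distance(table, comparison)
    ratios: list[ExtractedRatio] = []
    for (a, b), _score in zip(chosen, scores):
        # orient so the pooled geometric-mean ratio is >= 1
        if pooled_mean[a] - pooled_mean[b] >= 0:
            num, den = a, b
        else:
            num, den = b, a
        d_marg = marg[(a, b)]
        r1 = _ranges_for_members(table, comparison.members_1, cols[num], cols[den])
        r2 = _ranges_for_members(table, comparison.members_2, cols[num], cols[den])
        if r1 is None or r2 is None:
            warnings.warn(f"no non-imputed specimens for range of "
                          f"{cols[num]}:{cols[den]}", stacklevel=2)
            r1 = r1 or (float("nan"), float("nan"))
            r2 = r2 or (float("nan"), float("nan"))
        lo, hi = max(r1[0], r2[0]), min(r1[1], r2[1])
        ratios.append(ExtractedRatio(
            numerator=cols[num], denominator=cols[den],
            D=float(d_marg),
            delta=float(d_size / d_marg) if d_marg > 0 else float("nan"),
            range_1=r1, range_2=r2,
            overlap_flag=bool(hi > lo),
            starred=_overlap_small(r1, r2)))
    max_d = max(marg.values())
    return RatioExtractionResult(comparison, ratios, float(d_size),
                                 low_separation=bool(max_d < 1.0),
                                 skipped_pairs=skipped)


def table2_report(table: MeasurementTable,
                  comparisons: list[GroupComparison],
                  n_ratios: int = 2) -> pd.DataFrame:
    """Report of best ratios per comparison, one row per extracted ratio.

    Columns mirror a published best-ratio table: comparison, ratio, the two
    group ranges (2 decimals), D and δ (2 decimals), and a star when the
    ranges have very little or no overlap (overlap ≤ 5% of the union).
    """
    rows = []
    for comp in comparisons:
        res = extract_best_ratios(table, comp, n_ratios=n_ratios)
        for er in res.ratios:
            star = "*" if er.starred else ""
            rows.append({
                "comparison": f"{comp.label_1} - {comp.label_2}",
                "ratio": star + er.name,
                "range_1": f"{er.range_1[0]:.2f}-{er.range_1[1]:.2f}",
                "range_2": f"{er.range_2[0]:.2f}-{er.range_2[1]:.2f}",
                "D": f"{er.D:.2f}",
                "delta": f"{er.delta:.2f}",
            })
    return pd.DataFrame(rows, columns=["comparison", "ratio", "range_1",
                                       "range_2", "D", "delta"])


def report_to_text(report: pd.DataFrame) -> str:
    """Aligned plain-text rendering of :func:`table2_report` output."""
    buf = io.StringIO()
    widths = {c: max(len(c), *(len(str(v)) for v in report[c]))
              for c in report.columns} if len(report) else {c: len(c) for c in report.columns}
    buf.write("  ".join(c.ljust(widths[c]) for c in report.columns) + "\n")
    for _, row in report.iterrows():
        buf.write("  ".join(str(row[c]).ljust(widths[c]) for c in report.columns) + "\n")
    return buf.getvalue()
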