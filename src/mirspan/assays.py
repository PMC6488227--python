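"""Quantitative assay statistics: ChIP-qPCR percent input, comparative qPCR
(ddCt) fold changes, the exact Mann-Whitney U test for small groups, and
Pearson co-expression.

Percent input expresses immunoprecipitated DNA relative to the dilution-
adjusted input aliquot: with an input fraction f, the input Ct is first
shifted by -log2(1/f) to the scale of the whole chromatin pool, and
percent = 100 * 2^(adjusted_input_ct - ct_ip). Amplification efficiency is
fixed at 2.0 per cycle throughout (comparative TaqMan assays without an
efficiency calibration).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from functools import lru_cache
from itertools import combinations

import numpy as np
import pandas as pd
from scipy.stats import mannwhitneyu, pearsonr, rankdata

from .errors import ValidationError

MAX_EXACT_COMBINATIONS = 200_000


@dataclass
class ChipMeasurement:
    """One ChIP-qPCR measurement: IP and input Ct for a sample/antibody/region."""

    sample_id: str
    antibody: str
    region: str
    ct_ip: float
    ct_input: float
    input_fraction: float = 0.1

    def __post_init__(self):
        for name in ("ct_ip", "ct_input"):
            v = getattr(self, name)
            if not math.isfinite(v) or v <= 0:
                raise ValidationError(f"{name} must be finite and positive, got {v}")
        if not 0 < self.input_fraction <= 1:
            raise ValidationError(
                f"input_fraction must be in (0, 1], got {self.input_fraction}")


@dataclass
class QpcrMeasurement:
    """One comparative qPCR measurement: target and reference-assay Ct."""

    sample_id: str
    group: str
    ct_target: float
    ct_reference: float

    def __post_init__(self):
        for name in ("ct_target", "ct_reference"):
            v = getattr(self, name)
            if not math.isfinite(v) or v <= 0:
                raise ValidationError(f"{name} must be finite and positive, got {v}")

    @property
    def delta_ct(self) -> float:
        return self.ct_target - self.ct_reference


def percent_input(m: ChipMeasurement) -> float:
    """Percent Input of one ChIP measurement.

    adjusted_input_ct = ct_input - log2(1/input_fraction);
    percent = 100 * 2**(adjusted_input_ct - ct_ip). Invariant to adding the
    same constant to both Ct values.
    """
    adjusted = m.ct_input - math.log2(1.0 / m.input_fraction)
    return 100.0 * 2.0 ** (adjusted - m.ct_ip)


def relative_expression(m: QpcrMeasurement) -> float:
    """Per-sample relative expression 2**-(ct_target - ct_reference)."""
    return 2.0 ** (-m.delta_ct)


def ddct_fold(group_a, group_b) -> float:
    """ddCt fold change of group_a relative to group_b: 2**-(dCt_a - dCt_b),
    with dCt the group mean of per-sample ct_target - ct_reference."""
    if not group_a or not group_b:
        raise ValidationError("ddct_fold requires two non-empty groups")
    da = float(np.mean([m.delta_ct for m in group_a]))
    db = float(np.mean([m.delta_ct for m in group_b]))
    return 2.0 ** (-(da - db))


@dataclass
class MannWhitneyResult:
    u: float
    p_value: float
    approximate: bool

    def __iter__(self):  # allow tuple unpacking (u, p)
        return iter((self.u, self.p_value))


@lru_cache(maxsize=64)
def _combination_matrix(n_total: int, n_x: int) -> np.ndarray:
    """All index subsets of size n_x from n_total items, one row each."""
    return np.array(list(combinations(range(n_total), n_x)), dtype=np.intp)


def mann_whitney_exact(x, y, max_exact_combinations: int = MAX_EXACT_COMBINATIONS):
    """Mann-Whitney U with an exact permutation p-value for small groups.

    U counts pairs with x_i > y_j plus half of the ties. The exact two-sided
    p is the doubled smaller tail of the U distribution over all
    C(n_x+n_y, n_x) group labelings of the pooled data (capped at 1); ties are
    handled naturally because the enumeration conditions on the pooled values.
    When the labeling count exceeds ``max_exact_combinations`` the
    tie-corrected normal approximation is used instead and flagged via
    ``approximate``.
    """
    x = np.asarray(list(x), dtype=float)
    y = np.asarray(list(y), dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValidationError("both groups must be non-empty")
    nx_, ny_ = x.size, y.size
    if math.comb(nx_ + ny_, nx_) > max_exact_combinations:
        stat, p = mannwhitneyu(x, y, alternative="two-sided", method="asymptotic")
        return MannWhitneyResult(u=float(stat), p_value=float(p), approximate=True)
    pooled = np.concatenate([x, y])
    ranks = rankdata(pooled)  # midranks, so rank sums absorb ties as 1/2
    offset = nx_ * (nx_ + 1) / 2.0
    u_obs = float(ranks[:nx_].sum() - offset)
    combos = _combination_matrix(nx_ + ny_, nx_)
    u_all = ranks[combos].sum(axis=1) - offset
    n_tot = u_all.size
    lower = np.count_nonzero(u_all <= u_obs + 1e-9) / n_tot
    upper = np.count_nonzero(u_all >= u_obs - 1e-9) / n_tot
    p = min(1.0, 2.0 * min(lower, upper))
    return MannWhitneyResult(u=u_obs, p_value=p, approximate=False)


def pearson_r(x, y) -> float:
    """Product-moment correlation; requires equal lengths >= 3 and nonzero
    variance in both variables."""
    x = np.asarray(list(x), dtype=float)
    y = np.asarray(list(y), dtype=float)
    if x.size != y.size:
        raise ValidationError("pearson_r requires equal-length inputs")
    if x.size < 3:
        raise ValidationError("pearson_r requires at least 3 observations")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValidationError("pearson_r is undefined for zero-variance input")
    return float(pearsonr(x, y)[0])


# ---------------------------------------------------------------------------
# Ct-table interfaces (tab-separated with a single header row)

CHIP_COLUMNS = ["sample_id", "group", "antibody", "region", "ct_ip", "ct_input",
                "input_fraction"]
QPCR_COLUMNS = ["sample_id", "group", "target", "reference", "ct_target",
                "ct_reference"]


def load_chip_table(path) -> pd.DataFrame:
    table = pd.read_csv(path, sep="\t")
    missing = [c for c in CHIP_COLUMNS if c not in table.columns]
    if missing:
        raise ValidationError(f"ChIP table {path} is missing columns {missing}")
    return table


def load_qpcr_table(path) -> pd.DataFrame:
    table = pd.read_csv(path, sep="\t")
    missing = [c for c in QPCR_COLUMNS if c not in table.columns]
    if missing:
        raise ValidationError(f"qPCR table {path} is missing columns {missing}")
    return table


def chip_percent_input_summary(table: pd.DataFrame) -> pd.DataFrame:
    """Per-row percent input plus per antibody/region group comparison
    (exact Mann-Whitney between the two groups when exactly two exist)."""
    table = table.copy()
    table["percent_input"] = [
        percent_input(ChipMeasurement(
            sample_id=str(r.sample_id), antibody=str(r.antibody),
            region=str(r.region), ct_ip=float(r.ct_ip),
            ct_input=float(r.ct_input), input_fraction=float(r.input_fraction)))
        for r in table.itertuples()
    ]
    rows = []
    for (antibody, region), sub in table.groupby(["antibody", "region"], sort=True):
        groups = sorted(sub["group"].unique())
        row = {"antibody": antibody, "region": region}
        for g in groups:
            row[f"mean_percent_input_{g}"] = float(
                sub.loc[sub["group"] == g, "percent_input"].mean())
        if len(groups) == 2:
            a = sub.loc[sub["group"] == groups[0], "percent_input"]
            b = sub.loc[sub["group"] == groups[1], "percent_input"]
            res = mann_whitney_exact(a, b)
            row["mw_u"], row["mw_p"] = res.u, res.p_value
        rows.append(row)
    summary = pd.DataFrame(rows)
    summary.attrs["per_sample"] = table
    return summary


def qpcr_fold_summary(table: pd.DataFrame) -> pd.DataFrame:
    """Per target: ddCt fold change between the two groups (sorted group order,
    first relative to second) and exact Mann-Whitney p on per-sample relative
    expression."""
    rows = []
    for target, sub in table.groupby("target", sort=True):
        groups = sorted(sub["group"].unique())
        if len(groups) != 2:
            raise ValidationError(
                f"qPCR fold summary requires exactly 2 groups for {target!r}, "
                f"found {groups}")
        meas = {
            g: [QpcrMeasurement(str(r.sample_id), str(r.group),
                                float(r.ct_target), float(r.ct_reference))
                for r in sub[sub["group"] == g].itertuples()]
            for g in groups
        }
        rel = {g: [relative_expression(m) for m in meas[g]] for g in groups}
        res = mann_whitney_exact(rel[groups[0]], rel[groups[1]])
        rows.append({
            "target": target,
            "group_a": groups[0],
            "group_b": groups[1],
            "n_a": len(meas[groups[0]]),
            "n_b": len(meas[groups[1]]),
            "fold_a_vs_b": ddct_fold(meas[groups[0]], meas[groups[1]]),
            "mw_u": res.u,
            "mw_p": res.p_value,
        })
    return pd.DataFrame(rows)
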