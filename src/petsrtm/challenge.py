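"""Amphetamine-challenge pharmacodynamics on binding-potential tables.

The challenge statistics quantify displacement of a D2/D3 radioligand by
endogenous dopamine.  For each subject and region, with BP^BL the baseline
binding potential, BP^AMPH the value after the d-amphetamine challenge and
BP^AMPH+TAK the value when the challenge is preceded by the study drug:

    dBP^AMPH     = 100 * (1 - BP^AMPH / BP^BL)          (percent release)
    dBP^AMPH+TAK = 100 * (1 - BP^AMPH+TAK / BP^BL)
    ddBP         = 100 * (1 - dBP^AMPH+TAK / dBP^AMPH)  (percent attenuation)

Positive dBP means the challenge reduced binding; ddBP of 100% means the
pre-treatment abolished the challenge effect, 0% means no attenuation.
Group summaries average per-subject statistics (never ratios of group
means) and report classical Student t tests: paired two-tailed within
subjects, pooled-variance one-tailed between dose groups.
"""
from __future__ import annotations

import json
import warnings
from dataclasses import dataclass
from typing import NamedTuple

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "SCANS",
    "REGIONS",
    "DOSE_GROUPS",
    "BPTable",
    "ChallengeStudy",
    "ChallengeResults",
    "delta_bp",
    "delta_delta_bp",
    "paired_t_two_tailed",
    "unpaired_t_one_tailed",
    "summarize_challenge",
]

SCANS = ("baseline", "amph", "amph_tak")
REGIONS = ("Ca", "Pu", "VSt", "SN", "GP")
DOSE_GROUPS = ("20 mg", "40 mg", "none")

_BP_COLUMNS = ["subject_id", "dose_group", "scan", "region", "bp_nd"]


class BPTable:
    """Long-format table of BP_ND values: subject x scan x region.

    Wraps a validated DataFrame with columns ``subject_id, dose_group,
    scan, region, bp_nd``.  Scan labels are ``baseline`` / ``amph`` /
    ``amph_tak``; regions are the closed set Ca, Pu, VSt, SN, GP; unknown
    labels raise rather than being dropped silently.
    """

    def __init__(self, frame: pd.DataFrame):
        missing = [c for c in _BP_COLUMNS if c not in frame.columns]
        if missing:
            raise ValueError(f"BP table missing columns: {missing}")
        df = frame[_BP_COLUMNS].copy()
        bad_scan = set(df["scan"]) - set(SCANS)
        if bad_scan:
            raise ValueError(f"unknown scan labels: {sorted(bad_scan)}")
        bad_region = set(df["region"]) - set(REGIONS)
        if bad_region:
            raise ValueError(f"unknown region labels: {sorted(bad_region)}")
        bad_group = set(df["dose_group"]) - set(DOSE_GROUPS)
        if bad_group:
            raise ValueError(f"unknown dose groups: {sorted(bad_group)}")
        dup = df.duplicated(subset=["subject_id", "scan", "region"])
        if dup.any():
            raise ValueError(
                f"duplicate (subject, scan, region) records at rows {list(df.index[dup])}"
            )
        df["bp_nd"] = df["bp_nd"].astype(float)
        if not np.all(np.isfinite(df["bp_nd"])):
            raise ValueError("BP_ND values must be finite")
        if (df["bp_nd"] <= -1).any():
            raise ValueError("BP_ND values must exceed -1")
        groups = df.groupby("subject_id")["dose_group"].nunique()
        if (groups > 1).any():
            raise ValueError("a subject cannot belong to two dose groups")
        self.frame = df.reset_index(drop=True)

    @classmethod
    def from_records(cls, records) -> "BPTable":
        return cls(pd.DataFrame.from_records(records, columns=_BP_COLUMNS))

    @property
    def subjects(self) -> list:
        return sorted(self.frame["subject_id"].unique())

    @property
    def regions(self) -> list:
        return [r for r in REGIONS if r in set(self.frame["region"])]

    def dose_group_of(self) -> pd.Series:
        return self.frame.groupby("subject_id")["dose_group"].first()

    def wide(self) -> pd.DataFrame:
        """One row per (subject, region), one column per scan."""
        w = self.frame.pivot_table(
            index=["subject_id", "region"], columns="scan", values="bp_nd"
        ).reset_index()
        w.columns.name = None
        return w

    def __len__(self) -> int:
        return len(self.frame)

    def __eq__(self, other) -> bool:
        if not isinstance(other, BPTable):
            return NotImplemented
        a = self.frame.sort_values(_BP_COLUMNS[:4]).reset_index(drop=True)
        b = other.frame.sort_values(_BP_COLUMNS[:4]).reset_index(drop=True)
        return a.equals(b)


# ---------------------------------------------------------------------------
# elementary statistics

def delta_bp(bp_baseline, bp_post):
    """Percent reduction in BP_ND from baseline: 100*(1 - post/baseline).

    Positive values indicate a post-dose reduction.  Baseline must be
    strictly positive.
    """
    base = np.asarray(bp_baseline, dtype=float)
    post = np.asarray(bp_post, dtype=float)
    if np.any(base <= 0):
        raise ValueError("baseline BP_ND must be positive for a percent change")
    out = 100.0 * (1.0 - post / base)
    return float(out) if out.ndim == 0 else out


def delta_delta_bp(delta_amph, delta_amph_tak):
    """Percent attenuation of the challenge effect: 100*(1 - dTAK/dAMPH).

    100% is complete abolition of the amphetamine effect, 0% no
    attenuation; values outside [0, 100] are legitimate.  Where the
    amphetamine effect is exactly zero the ratio is undefined and NaN is
    returned with a warning (downstream group means exclude it).
    """
    da = np.asarray(delta_amph, dtype=float)
    dt = np.asarray(delta_amph_tak, dtype=float)
    zero = da == 0
    if np.any(zero):
        warnings.warn(
            "delta BP_ND (amph) is zero for some records; their attenuation is "
            "undefined and returned as NaN",
            RuntimeWarning,
            stacklevel=2,
        )
    with np.errstate(divide="ignore", invalid="ignore"):
        out = np.where(zero, np.nan, 100.0 * (1.0 - dt / da))
    return float(out) if out.ndim == 0 else out


class TTestResult(NamedTuple):
    statistic: float
    df: int
    pvalue: float


def paired_t_two_tailed(x, y) -> TTestResult:
    """Classical paired Student t test on the differences x - y.

    Degenerate cases: identical pairs give (t=0, p=1); zero-variance
    differences with a nonzero mean give the limit p=0.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("paired samples must be 1-D and of equal length")
    n = x.size
    if n < 2:
        raise ValueError("need at least two pairs")
    d = x - y
    df = n - 1
    sd = d.std(ddof=1)
    if sd == 0:
        if d.mean() == 0:
            return TTestResult(0.0, df, 1.0)
        return TTestResult(np.inf if d.mean() > 0 else -np.inf, df, 0.0)
    t = d.mean() / (sd / np.sqrt(n))
    p = 2.0 * stats.t.sf(abs(t), df)
    return TTestResult(float(t), df, float(p))


def unpaired_t_one_tailed(x_low, x_high, welch: bool = False) -> TTestResult:
    """One-tailed two-sample t test for alternative mean(x_high) > mean(x_low).

    Pooled-variance Student t by default (df = n1 + n2 - 2); set
    ``welch=True`` for the unequal-variance form.
    """
    a = np.asarray(x_low, dtype=float)
    b = np.asarray(x_high, dtype=float)
    if a.ndim != 1 or b.ndim != 1 or a.size < 2 or b.size < 2:
        raise ValueError("need at least two observations per group")
    n1, n2 = a.size, b.size
    diff = b.mean() - a.mean()
    v1, v2 = a.var(ddof=1), b.var(ddof=1)
    if welch:
        se2 = v1 / n1 + v2 / n2
        if se2 == 0:
            df = n1 + n2 - 2
            return TTestResult(*_degenerate_one_tailed(diff, df))
        df_w = se2**2 / ((v1 / n1) ** 2 / (n1 - 1) + (v2 / n2) ** 2 / (n2 - 1))
        t = diff / np.sqrt(se2)
        return TTestResult(float(t), int(round(df_w)), float(stats.t.sf(t, df_w)))
    df = n1 + n2 - 2
    pooled = ((n1 - 1) * v1 + (n2 - 1) * v2) / df
    if pooled == 0:
        return TTestResult(*_degenerate_one_tailed(diff, df))
    t = diff / np.sqrt(pooled * (1.0 / n1 + 1.0 / n2))
    p = stats.t.sf(t, df)
    return TTestResult(float(t), df, float(p))


def _degenerate_one_tailed(diff: float, df: int):
    if diff == 0:
        return 0.0, df, 0.5
    return (np.inf, df, 0.0) if diff > 0 else (-np.inf, df, 1.0)


# ---------------------------------------------------------------------------
# study-level model

class ChallengeStudy:
    """Group analysis of a three-scan challenge study from a BP_ND table.

    Usage::

        study = ChallengeStudy(bp_table)
        res = study.fit(grouping="by_dose")
        print(res.summary())

    ``fit`` computes per-subject dBP and ddBP first, then group means/SDs
    (SD with the n-1 denominator) and the study's t tests per region:

    * paired two-tailed, baseline vs post-amphetamine BP_ND;
    * paired two-tailed, dBP^AMPH vs dBP^AMPH+TAK;
    * unpaired one-tailed, ddBP between the low- and high-dose groups.
    """

    def __init__(self, bp_table: BPTable):
        if not isinstance(bp_table, BPTable):
            bp_table = BPTable(bp_table)
        self.bp_table = bp_table

    @classmethod
    def from_dataframe(cls, frame: pd.DataFrame) -> "ChallengeStudy":
        return cls(BPTable(frame))

    def subject_effects(self) -> pd.DataFrame:
        """Per (subject, region): dBP^AMPH, dBP^AMPH+TAK, ddBP in percent.

        Subjects missing the baseline scan for a region are excluded with
        a warning; a missing post scan leaves that statistic NaN.
        """
        w = self.bp_table.wide()
        groups = self.bp_table.dose_group_of()
        for scan in SCANS:
            if scan not in w.columns:
                w[scan] = np.nan
        no_base = w["baseline"].isna() | (w["baseline"] <= 0)
        if no_base.any():
            bad = w.loc[no_base, ["subject_id", "region"]].to_records(index=False)
            warnings.warn(
                f"excluding {no_base.sum()} subject-region cells without a "
                f"usable baseline scan: {list(bad)[:5]}",
                RuntimeWarning,
                stacklevel=2,
            )
            w = w[~no_base]
        out = w[["subject_id", "region"]].copy()
        out["dose_group"] = out["subject_id"].map(groups)
        out["bp_baseline"] = w["baseline"].to_numpy()
        out["bp_amph"] = w["amph"].to_numpy()
        out["bp_amph_tak"] = w["amph_tak"].to_numpy()
        base = w["baseline"].to_numpy()
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            out["dbp_amph"] = 100.0 * (1.0 - w["amph"].to_numpy() / base)
            out["dbp_amph_tak"] = 100.0 * (1.0 - w["amph_tak"].to_numpy() / base)
            da = out["dbp_amph"].to_numpy()
            dt = out["dbp_amph_tak"].to_numpy()
            out["ddbp"] = np.where(da == 0, np.nan, 100.0 * (1.0 - dt / da))
        if np.any((da == 0) & np.isfinite(dt)):
            warnings.warn(
                "zero amphetamine effect for some subject-region cells; their "
                "attenuation is undefined and excluded from group means",
                RuntimeWarning,
                stacklevel=2,
            )
        return out.reset_index(drop=True)

    def fit(self, grouping: str = "by_dose", welch: bool = False) -> "ChallengeResults":
        if grouping not in ("all", "by_dose"):
            raise ValueError(f"unknown grouping {grouping!r}")
        eff = self.subject_effects()
        has_tak = eff["dbp_amph_tak"].notna().any()

        rows = []
        for region, sub in eff.groupby("region", sort=False):
            cells = [("all", sub)]
            if grouping == "by_dose":
                for g in ("20 mg", "40 mg"):
                    gsub = sub[sub["dose_group"] == g]
                    if len(gsub):
                        cells.append((g, gsub))
            for label, cell in cells:
                da = cell["dbp_amph"].dropna()
                dd = cell["ddbp"].dropna()
                rows.append(
                    {
                        "region": region,
                        "group": label,
                        "n": len(cell),
                        "dbp_amph_mean": da.mean() if len(da) else np.nan,
                        "dbp_amph_sd": da.std(ddof=1) if len(da) > 1 else np.nan,
                        "ddbp_mean": dd.mean() if len(dd) else np.nan,
                        "ddbp_sd": dd.std(ddof=1) if len(dd) > 1 else np.nan,
                        "n_ddbp": len(dd),
                    }
                )
        summary = pd.DataFrame(rows)
        summary["region"] = pd.Categorical(summary["region"], categories=REGIONS, ordered=True)
        summary = summary.sort_values(["region", "group"]).reset_index(drop=True)

        tests = []
        for region, sub in eff.groupby("region", sort=False):
            rec = {"region": region}
            paired = sub.dropna(subset=["bp_baseline", "bp_amph"])
            if len(paired) >= 2:
                r = paired_t_two_tailed(paired["bp_baseline"], paired["bp_amph"])
                rec.update(p_amph_vs_baseline=r.pvalue, t_amph_vs_baseline=r.statistic)
            if has_tak:
                dpair = sub.dropna(subset=["dbp_amph", "dbp_amph_tak"])
                if len(dpair) >= 2:
                    r = paired_t_two_tailed(dpair["dbp_amph"], dpair["dbp_amph_tak"])
                    rec.update(p_attenuation=r.pvalue, t_attenuation=r.statistic)
                if grouping == "by_dose":
                    lo = sub[(sub["dose_group"] == "20 mg")]["ddbp"].dropna()
                    hi = sub[(sub["dose_group"] == "40 mg")]["ddbp"].dropna()
                    if len(lo) >= 2 and len(hi) >= 2:
                        r = unpaired_t_one_tailed(lo, hi, welch=welch)
                        rec.update(p_dose_effect=r.pvalue, t_dose_effect=r.statistic)
            tests.append(rec)
        tests = pd.DataFrame(tests)
        tests["region"] = pd.Categorical(tests["region"], categories=REGIONS, ordered=True)
        tests = tests.sort_values("region").reset_index(drop=True)

        if not has_tak:
            warnings.warn(
                "no amph_tak scans found: attenuation columns are all-NaN, "
                "only the amphetamine-challenge summary is meaningful",
                RuntimeWarning,
                stacklevel=2,
            )
        return ChallengeResults(self, eff, summary, tests, grouping)


@dataclass
class ChallengeResults:
    """Group means, SDs and significance tests of a challenge study."""

    model: ChallengeStudy
    subject_effects: pd.DataFrame
    summary_frame: pd.DataFrame
    tests: pd.DataFrame
    grouping: str

    def summary(self) -> str:
        lines = [
            "Amphetamine-challenge summary (percent, mean (SD))",
            "=" * 66,
            f"{'region':<7}{'group':<9}{'n':>3}  {'dBP_amph':>14}  {'ddBP':>14}",
            "-" * 66,
        ]
        for _, r in self.summary_frame.iterrows():
            dbp = f"{r.dbp_amph_mean:6.1f} ({r.dbp_amph_sd:4.1f})"
            dd = (
                f"{r.ddbp_mean:6.1f} ({r.ddbp_sd:4.1f})"
                if np.isfinite(r.ddbp_mean)
                else "      --"
            )
            lines.append(f"{r.region:<7}{r.group:<9}{r.n:>3}  {dbp:>14}  {dd:>14}")
        lines.append("-" * 66)
        lines.append("paired/unpaired t tests per region (p values):")
        for _, r in self.tests.iterrows():
            parts = [f"{r.region:<4}"]
            if "p_amph_vs_baseline" in r and np.isfinite(r.get("p_amph_vs_baseline", np.nan)):
                parts.append(f"baseline vs amph p={r.p_amph_vs_baseline:.4f}")
            if np.isfinite(r.get("p_attenuation", np.nan)):
                parts.append(f"attenuation p={r.p_attenuation:.4f}")
            if np.isfinite(r.get("p_dose_effect", np.nan)):
                parts.append(f"dose effect (one-tailed) p={r.p_dose_effect:.4f}")
            lines.append("  " + "  ".join(parts))
        lines.append("=" * 66)
        return "\n".join(lines)

    def to_json(self) -> str:
        payload = {
            "grouping": self.grouping,
            "summary": self.summary_frame.assign(
                region=self.summary_frame["region"].astype(str)
            ).to_dict(orient="records"),
            "tests": self.tests.assign(
                region=self.tests["region"].astype(str)
            ).to_dict(orient="records"),
        }
        return json.dumps(payload, indent=2, allow_nan=True)

    def input_rounding_bound(self, step: float = 0.005) -> pd.DataFrame:
        """Worst-case shift of each group mean if every input BP_ND is
        rounded to within ``step`` of its true value.

        With b, a, t the baseline, post-challenge and post-challenge+drug
        BP_ND of a subject, dBP = 100(1 - a/b) and ddBP = 100(t - a)/(b - a);
        the bound sums |d(stat)/d(input)| * step over the inputs and averages
        over the subjects of the cell.  Attenuation ratios with small
        challenge effects are far more rounding-sensitive than dBP itself.
        """
        eff = self.subject_effects
        b = eff["bp_baseline"].to_numpy()
        a = eff["bp_amph"].to_numpy()
        t = eff["bp_amph_tak"].to_numpy()
        with np.errstate(divide="ignore", invalid="ignore"):
            dbp_bound = step * 100.0 * (1.0 / b + np.abs(a) / b**2)
            den = b - a
            ddbp_bound = (
                step
                * 100.0
                * (np.abs(1.0 / den) + np.abs(t - b) / den**2 + np.abs(t - a) / den**2)
            )
        per_subject = eff[["subject_id", "region", "dose_group"]].copy()
        per_subject["dbp_bound"] = dbp_bound
        per_subject["ddbp_bound"] = ddbp_bound
        rows = []
        for _, r in self.summary_frame.iterrows():
            cell = per_subject[per_subject["region"] == r.region]
            if r.group != "all":
                cell = cell[cell["dose_group"] == r.group]
            rows.append(
                {
                    "region": r.region,
                    "group": r.group,
                    "dbp_bound": cell["dbp_bound"].mean(),
                    "ddbp_bound": cell["ddbp_bound"].mean(),
                }
            )
        return pd.DataFrame(rows)

    def plot(self, region: str = "Pu", ax=None):
        """Strip plot of per-subject attenuation values by dose group."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        eff = self.subject_effects
        sub = eff[eff["region"] == region]
        for i, g in enumerate(("20 mg", "40 mg")):
            vals = sub[sub["dose_group"] == g]["ddbp"].dropna()
            ax.plot(np.full(len(vals), i), vals, "o", alpha=0.7, label=g)
        ax.set_xticks([0, 1], ["20 mg", "40 mg"])
        ax.set_ylabel("ddBP_ND (%)")
        ax.set_title(region)
        return ax


def summarize_challenge(table: BPTable, grouping: str = "by_dose") -> ChallengeResults:
    """Functional wrapper over :class:`ChallengeStudy`."""
    return ChallengeStudy(table).fit(grouping=grouping)
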