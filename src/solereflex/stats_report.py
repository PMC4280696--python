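"""Per-subject aggregation, paired one-sided t-tests and report tables.

The experiment summarizes each subject by one value per condition x muscle
(%MVC RMS during stimulation, plate-induced angle change in degrees, or raw
rest/MVC RMS in µV).  Aggregates are mean ± sample SD across subjects; the
slow-versus-fast comparison at 3.5 bar is a paired one-sided t-test per
condition ("fast > slow", alpha 0.05), with the four conditions treated as
separate experiments (no multiplicity correction, by design).

The published per-subject tables ship as package fixtures so the aggregate
rows and p-values can be reproduced exactly.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass
from importlib import resources
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

FIXTURE_FILES = {
    "rest_mvc": "table3_rest_mvc_uv.csv",
    "slow_rms": "table5_slow_rms_pctmvc.csv",
    "angle_change": "table6_angle_change_deg.csv",
    "fast_rms": "table7_fast_rms_pctmvc.csv",
}

#: The slow/fast RMS tables pair column-for-column; the angle/rest tables
#: have no paired counterpart.
PAIRED_CONDITIONS = ("heel_ta", "heel_sol", "forefoot_ta", "forefoot_sol")


def load_fixture(name: str) -> pd.DataFrame:
    """Load one published per-subject table by short name.

    Names: ``rest_mvc`` (rest and MVC RMS, µV), ``slow_rms`` / ``fast_rms``
    (%MVC RMS during 3.5 bar stimuli), ``angle_change`` (degrees).
    Indexed by subject id.
    """
    try:
        fname = FIXTURE_FILES[name]
    except KeyError:
        raise KeyError(f"unknown fixture {name!r}; choose from {sorted(FIXTURE_FILES)}")
    with resources.files("solereflex.fixtures").joinpath(fname).open() as fh:
        return pd.read_csv(fh, index_col="subject")


def round_half_away(x: float, decimals: int = 2) -> float:
    """Round half away from zero (so 189.155 -> 189.16, -1.325 -> -1.33)."""
    q = 10.0**decimals
    return math.copysign(math.floor(abs(x) * q + 0.5), x) / q


@dataclass(frozen=True)
class AggregateRow:
    """Across-subject mean ± SD for one condition and muscle."""

    condition: str
    mean: float
    sd: float
    n: int

    @property
    def display(self) -> str:
        return f"{round_half_away(self.mean):.2f} ± {round_half_away(self.sd):.2f}"


@dataclass(frozen=True)
class PairedTestResult:
    """One-sided paired t-test, direction fixed to 'fast > slow'."""

    condition: str
    t: float
    df: int
    p: float
    direction: str = "greater"

    def __post_init__(self) -> None:
        if not 0.0 <= self.p <= 1.0:
            raise ValueError("p must be in [0, 1]")


def aggregate(values: Sequence[float], condition: str = "") -> AggregateRow:
    """Across-subject mean and sample SD (n-1 denominator)."""
    arr = np.asarray(values, float)
    if arr.size < 2:
        raise ValueError("need at least two subjects to aggregate")
    return AggregateRow(
        condition=condition,
        mean=float(arr.mean()),
        sd=float(arr.std(ddof=1)),
        n=int(arr.size),
    )


def paired_t_one_sided(
    slow: Sequence[float], fast: Sequence[float], condition: str = ""
) -> PairedTestResult:
    """Paired one-sided t-test of fast > slow on per-subject values.

    d_i = fast_i - slow_i; t = mean(d) / (sd(d)/sqrt(n)); p is the upper
    tail of Student's t with n-1 degrees of freedom.  Zero difference
    variance leaves t (hence p) undefined and raises ``ValueError``.
    """
    slow = np.asarray(slow, float)
    fast = np.asarray(fast, float)
    if slow.shape != fast.shape or slow.ndim != 1:
        raise ValueError("slow and fast must be equal-length 1-D vectors")
    n = slow.size
    if n < 2:
        raise ValueError("need at least two paired observations")
    d = fast - slow
    sd = d.std(ddof=1)
    if sd == 0.0:
        raise ValueError("zero difference variance: t-test undefined")
    t = float(d.mean() / (sd / math.sqrt(n)))
    p = float(sps.t.sf(t, df=n - 1))
    return PairedTestResult(condition=condition, t=t, df=n - 1, p=p)


def significance_flag(result: PairedTestResult, alpha: float = 0.05) -> bool:
    """Strict inequality: significant iff p < alpha."""
    return result.p < alpha


def fixture_aggregates() -> dict[str, dict[str, AggregateRow]]:
    """Mean ± SD for every column of every packaged per-subject table."""
    out: dict[str, dict[str, AggregateRow]] = {}
    for name in FIXTURE_FILES:
        df = load_fixture(name)
        out[name] = {
            col: aggregate(df[col].to_numpy(), condition=col) for col in df.columns
        }
    return out


def fixture_paired_tests() -> dict[str, PairedTestResult]:
    """Slow-vs-fast paired t-tests on the packaged 3.5 bar RMS tables."""
    slow = load_fixture("slow_rms")
    fast = load_fixture("fast_rms")
    return {
        cond: paired_t_one_sided(slow[cond].to_numpy(), fast[cond].to_numpy(), cond)
        for cond in PAIRED_CONDITIONS
    }


def _subject_sort_key(s: str):
    # S1..S10 ordering; fall back to lexicographic for other id schemes
    if isinstance(s, str) and s[:1] in "Ss" and s[1:].isdigit():
        return (0, int(s[1:]))
    return (1, str(s))


def build_report(
    summaries: Mapping[str, pd.DataFrame],
    tests: Mapping[str, PairedTestResult] | None = None,
    out_dir: str | Path = "report",
) -> dict:
    """Emit per-table CSVs (subject rows + Mean ± SD row) and a JSON bundle.

    ``summaries`` maps table name to a per-subject DataFrame (subjects in
    the index, condition-muscle columns).  Subject sets must agree across
    tables; subjects are sorted so output is order-independent.  Where a
    test result matches a table's columns, a p-value row is appended.
    Full-precision aggregates and tests go to ``report.json``; table CSVs
    hold the 2-decimal display values.
    """
    tests = dict(tests or {})
    subject_sets = {name: set(df.index) for name, df in summaries.items()}
    reference = set.union(*subject_sets.values()) if subject_sets else set()
    mismatched = {
        name: sorted(reference - subjects | subjects - reference, key=_subject_sort_key)
        for name, subjects in subject_sets.items()
        if subjects != reference
    }
    if mismatched:
        raise ValueError(f"inconsistent subject sets across tables: {mismatched}")
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    bundle: dict = {
        "note": (
            "fast-vs-slow p-values pair the slow-stimulus RMS table with the "
            "fast-stimulus RMS table (the published footnote citing the "
            "occurrence table is a typo)"
        ),
        "aggregates": {},
        "tests": {},
    }
    for name, df in summaries.items():
        df = df.loc[sorted(df.index, key=_subject_sort_key)]
        rows = df.round(2).astype(float)
        agg = {col: aggregate(df[col].to_numpy(), col) for col in df.columns}
        display = rows.copy()
        display.loc["Mean"] = [round_half_away(agg[c].mean) for c in df.columns]
        display.loc["SD"] = [round_half_away(agg[c].sd) for c in df.columns]
        cols_tested = [c for c in df.columns if c in tests]
        if cols_tested == list(df.columns):
            display.loc["p_value"] = [round(tests[c].p, 4) for c in df.columns]
        display.to_csv(out_dir / f"{name}.csv")
        bundle["aggregates"][name] = {
            c: {"mean": a.mean, "sd": a.sd, "n": a.n} for c, a in agg.items()
        }
    for cond, res in tests.items():
        bundle["tests"][cond] = {
            "t": res.t,
            "df": res.df,
            "p": res.p,
            "direction": res.direction,
            "significant_at_0.05": significance_flag(res),
        }
    with open(out_dir / "report.json", "w") as fh:
        json.dump(bundle, fh, indent=1)
    return bundle
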