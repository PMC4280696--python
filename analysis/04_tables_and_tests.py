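"""Reproduce the published aggregate tables and paired t-tests.

Aggregates the packaged per-subject tables (rest/MVC RMS, slow and fast
%MVC RMS at 3.5 bar, plate-induced angle changes) into their Mean ± SD
rows and runs the four slow-vs-fast paired one-sided t-tests, writing the
report tables and a machine-readable JSON bundle.
"""

from pathlib import Path

from solereflex.stats_report import (
    FIXTURE_FILES,
    build_report,
    fixture_paired_tests,
    load_fixture,
)

OUT = Path(__file__).resolve().parent.parent / "results" / "tables"

summaries = {name: load_fixture(name) for name in FIXTURE_FILES}
tests = fixture_paired_tests()
bundle = build_report(summaries, tests, out_dir=OUT)

for table, cols in bundle["aggregates"].items():
    cells = {c: f"{v['mean']:.2f} ± {v['sd']:.2f}" for c, v in cols.items()}
    print(f"{table}: {cells}")
print("paired one-sided t-tests (fast > slow):")
for cond, res in bundle["tests"].items():
    verdict = "significant" if res["significant_at_0.05"] else "trend"
    print(f"  {cond}: t = {res['t']:.3f}, df = {res['df']}, p = {res['p']:.4f} ({verdict})")
print(f"wrote tables to {OUT}")
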