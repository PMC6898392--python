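"""Run the whole virtual study with one call and read the report.

Equivalent to `podosim all --scenario fafa-vs-control --out scratch/run --seed 3`.
"""

import json
from pathlib import Path

from podosim import run_pipeline

out = Path("scratch/example_run")
manifest = run_pipeline("fafa-vs-control", out, seed=3)
report = json.loads((out / "report.json").read_text())

print(f"outputs in {out} (config hash {manifest.config_hash[:12]})")
print("glomerular volume fold by week:")
for week, comp in sorted(report["volume_comparisons"].items(), key=lambda kv: int(kv[0])):
    print(f"  week {week}: {comp['volume_fold']:.2f}-fold (Mann-Whitney p={comp['volume_mw_p']:.3f})")
print("albuminuria relationships (fa/fa):")
for name, rel in report["albumin_relationships"].items():
    print(f"  albumin vs {name}: R^2={rel['r_squared']:.2f}")
budget = report["budget"]["fafa"]
print(f"podocyte budget: {budget['percent_accounted']:.0f}% of loss accounted in urine")
# The report holds the scenario analogs of the study's group comparisons:
# fold-changes, slopes, R^2 values, nonparametric p-values and the budget.
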