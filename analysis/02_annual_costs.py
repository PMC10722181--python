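"""Prevalence-based annual costing of the simulated cohort.

Annualizes each patient's person-month costs (x12; admission bill counted
once), values productivity losses by the human-capital approach, aggregates
the cohort cost table, and prints it with direct/indirect shares and the PPP
conversion.  Run 01_simulate_cohort.py first.
"""

from pathlib import Path

import pandas as pd

from hfcoi.cohort import default_cohort_config, read_cohort_csv
from hfcoi.costing import (
    DEFAULT_TOMAN_PER_PPP,
    aggregate_breakdown,
    annual_patient_cost,
    convert_to_ppp,
)
from hfcoi.report import render_breakdown

OUT = Path(__file__).resolve().parents[1] / "results"
records = read_cohort_csv(OUT / "cohort.csv")
wages = default_cohort_config().wages

costs = [annual_patient_cost(r, wages) for r in records]
b = aggregate_breakdown(costs, [r.nyha_class for r in records])

print(render_breakdown(b, toman_per_ppp=DEFAULT_TOMAN_PER_PPP))
print(f"grand total {b.grand_total:,.1f} Toman "
      f"({convert_to_ppp(b.grand_total):,.2f} PPP$) per patient-year; "
      f"{b.share_indirect}% indirect / {b.share_direct}% direct")

rows = pd.DataFrame({"mean": b.component_means, "sd": b.component_sds})
rows.to_csv(OUT / "annual_breakdown.csv")
pd.DataFrame([{
    "id": c.id, "direct_total": c.direct_total,
    "indirect_total": c.indirect_total, "grand_total": c.grand_total}
    for c in costs]).to_csv(OUT / "annual_costs.csv", index=False)
print(f"wrote {OUT / 'annual_breakdown.csv'} and {OUT / 'annual_costs.csv'}")
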