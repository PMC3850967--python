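"""Quantify pathway relationships across the compendium.

Computes the Spearman correlation matrix over the five activity scores,
classifies every tumor into EZH2/HDAC4 activation quadrants, tests the
co-activation deficit against the independence expectation, and runs the
subtype ANOVA with enrichment among HDAC4-activated tumors.
"""

import json

import pandas as pd

from episig.pipeline import run_pipeline
from study_config import study_config

out = run_pipeline(study_config(), ["exclusivity"])
r = pd.read_csv(out / "exclusivity" / "spearman_r.tsv", sep="\t", index_col=0)
q = json.loads((out / "exclusivity" / "quadrant_summary.json").read_text())
a = json.loads((out / "exclusivity" / "subtype_association.json").read_text())
print("Spearman correlations between predicted activities:")
print(r.round(2))
print(f"\nEZH2/HDAC4 quadrants (n={q['n']}): both {q['counts']['both_active']}, "
      f"EZH2-only {q['counts']['a_only']}, HDAC4-only {q['counts']['b_only']}, "
      f"neither {q['counts']['neither']}")
print(f"observed co-activation {100*q['observed_coactivation']:.1f}% vs "
      f"expected {100*q['expected_coactivation']:.1f}% "
      f"(deficit p = {q['p_value']:.3g})")
print(f"HDAC4 subtype ANOVA F = {a['f_statistic']['HDAC4']:.1f} "
      f"(p = {a['p_value']['HDAC4']:.3g}); enrichment among activated: "
      + ", ".join(f"{k} {100*v:.0f}%" for k, v in a["enrichment"].items()))
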