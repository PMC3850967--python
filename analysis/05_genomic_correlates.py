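"""Link activity-defined extreme groups to genomic alterations.

Defines the EZH2-high/HDAC4-low vs EZH2-low/HDAC4-high tumor groups,
filters copy-number genes to group-specific gains/losses, runs the
sliding-window methylation test and calibrates its false-positive rate by
label shuffling.
"""

import json

import pandas as pd

from episig.pipeline import run_pipeline
from study_config import study_config

out = run_pipeline(study_config(), ["correlates"])
groups = json.loads((out / "correlates" / "extreme_groups.json").read_text())
status = pd.read_csv(out / "correlates" / "cnv_status.tsv", sep="\t",
                     index_col=0)["status"]
meth = pd.read_csv(out / "correlates" / "meth_windows.tsv", sep="\t",
                   index_col=0)
fpr = json.loads((out / "correlates" / "meth_fpr.json").read_text())
print(f"extreme groups: {len(groups['group1'])} EZH2-high/HDAC4-low vs "
      f"{len(groups['group2'])} EZH2-low/HDAC4-high tumors")
print("copy-number statuses:")
print(status.value_counts().to_string())
print(f"methylation windows kept at p<0.1: {int(meth['kept'].sum())} "
      f"of {len(meth)}; permutation FPR {100*fpr['mean_fraction']:.1f}% "
      f"(sd {100*fpr['sd_fraction']:.1f}%)")
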