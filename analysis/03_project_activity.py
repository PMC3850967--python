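"""Project the trained signatures onto the tumor compendium.

Produces per-tumor raw activation probabilities and within-dataset
log/min-max rescaled activity scores for all five pathways.
"""

import json

import pandas as pd

from episig.pipeline import run_pipeline
from study_config import study_config

out = run_pipeline(study_config(), ["predict"])
rescaled = pd.read_csv(out / "activity" / "activity_rescaled.tsv",
                       sep="\t", index_col=0)
meta = json.loads((out / "activity" / "activity.meta.json").read_text())
print(f"projected {rescaled.shape[1]} signatures onto {rescaled.shape[0]} tumors "
      f"(gene coverage: {meta['coverage']})")
print("rescaled activity summary:")
print(rescaled.describe().loc[["mean", "50%"]].round(3))
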