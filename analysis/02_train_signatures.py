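"""Normalize the training data, train all five signatures, validate by LOOCV.

Each signature selects 200 genes by the regularized two-class statistic,
summarizes them as an SVD metagene and fits the Bayesian probit; LOOCV
retrains the full procedure per held-out sample.
"""

import json

from episig.pipeline import run_pipeline
from study_config import study_config

out = run_pipeline(study_config(), ["preprocess", "train", "loocv"])
loocv = json.loads((out / "models" / "loocv.json").read_text())
print("LOOCV accuracy per pathway signature:")
for pw, res in loocv.items():
    if isinstance(res, dict) and "accuracy" in res:
        print(f"  {pw:6s} {res['accuracy']:.2f}")
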