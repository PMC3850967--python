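"""Shared configuration for the numbered analysis scripts.

One master seed drives every stochastic stage; artifacts accumulate under
``results/study`` so the scripts can be run one after another (01 -> 05)
or all at once via ``episig all --outdir results/study --seed 17``.
"""

from pathlib import Path

from episig.pipeline import default_config

RESULTS = Path(__file__).resolve().parent.parent / "results" / "study"


def study_config():
    return default_config(seed=17, outdir=str(RESULTS))
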