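"""Signal-detection analysis of simulated single-interval responses.

Trains a machine observer, simulates 10 observers that share its
decision rule but add Gaussian internal noise, and runs the human-data
analysis pipeline: hit/false-alarm rates, d' and response bias per
observer and condition, then across-observer means with SEM.
"""

import numpy as np
import pandas as pd

from shadowedge import GeneratorParams, features, lda, run_human_analysis, synth

dataset = synth.generate_dataset(25, GeneratorParams(), seed=3)
table = features.feature_table(dataset.patches)
model = lda.fit_lda(
    table[list(features.FEATURE_NAMES)].to_numpy(),
    table["category"].to_numpy(),
    feature_names=features.FEATURE_NAMES,
)

trials = pd.concat(
    [
        synth.simulate_observer(
            dataset, model, internal_noise_sd=2.0,
            rng=np.random.default_rng(100 + i), observer_id=f"sim-{i:02d}",
            feature_frame=table,
        )
        for i in range(10)
    ],
    ignore_index=True,
)
print(f"simulated {trials['observer_id'].nunique()} observers, "
      f"{len(trials)} trials total")

result = run_human_analysis(trials)
print("\ngroup table (mean d' +/- SEM across observers):")
print(result["group"].to_string(index=False))
print("\npaired Col - Lum d' difference per size (bootstrap 95% CI):")
print(result["paired"].to_string(index=False))
print(
    "\nEach simulated observer sees the color benefit: the Col condition\n"
    "keeps the chromatic features, the Lum condition zeroes them, and\n"
    "internal noise drags everyone's d' below the noiseless model's."
)
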