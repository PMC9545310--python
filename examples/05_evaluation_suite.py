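"""The evaluation indices on a controlled pair of ventilation maps.

Builds a "prediction" as truth + noise so every metric has a known
qualitative target: high Spearman, tertile Dice well above the 1/3
chance level, small MSE, and a low-attenuation region that matches the
reference's low tertile.
"""

import numpy as np

from ctvi import (
    PhantomParams,
    evaluate_case,
    generate_phantom,
    normalize_spect,
    summarize_cohort,
)
from ctvi.preprocess import spect_lung_mask

rng = np.random.default_rng(0)
rows = []
for seed in range(4):
    ct, vent, mask, truth = generate_phantom(PhantomParams(seed=seed))
    ref = normalize_spect(truth, mask)
    noisy = ref.with_data(ref.data * rng.lognormal(0, 0.15, ref.shape) * (mask.data == 1))
    m = evaluate_case(
        noisy, ref, mask, ct_hu=ct, spect_mask=spect_lung_mask(vent), case_id=f"case{seed}"
    )
    rows.append(m)

df = summarize_cohort(rows)
cols = ["case_id", "spearman_rs", "dsc_high", "dsc_moderate", "dsc_low", "mse",
        "non_defect_pct", "mask_dsc"]
print(df[cols].round(3).to_string(index=False))
print(
    "\nmask_dsc is the CT-mask vs 15%-of-max SPECT-mask overlap (registration\n"
    "quality); the last two rows are the cohort mean and SD."
)
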