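"""Template similarity as a pre-sorting indicator.

Generates two-fiber recordings whose between-template RMSE is set by
construction (morphing one base spike shape into another), recovers the
templates through the pipeline, and shows that supervised sorting accuracy
rises with template distance: similar templates are hard to sort.
"""

import numpy as np

from mngsort import (
    ClassifierSpec,
    SyntheticConfig,
    compute_templates,
    extract_aligned_waveforms,
    extract_features,
    generate_recording,
    make_template_pair,
    run_cv,
    template_distance,
)

print(f"{'generated RMSE':>14} {'recovered RMSE':>15} {'W_raw accuracy':>15}")
for target in (0.1, 0.3, 0.6, 0.9, 1.2):
    t0, t1 = make_template_pair(target, fs=10000.0)
    cfg = SyntheticConfig(n_fibers=2, n_sweeps=40, templates=(t0, t1),
                          noise_sd=0.5, seed=2)
    waveforms, _ = extract_aligned_waveforms(generate_recording(cfg))
    a, b = compute_templates(waveforms).values()
    recovered = template_distance(a, b, "rmse")
    acc = run_cv(extract_features(waveforms, "W_raw"),
                 ClassifierSpec(seed=0)).accuracy
    print(f"{target:>14.2f} {recovered:>15.3f} {acc:>15.3f}")

print("\nRecovered RMSE tracks the generated distance; accuracy climbs "
      "from near chance (similar templates) toward 1.0 (distinct "
      "templates) — the distance is a usable sortability indicator.")
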