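"""Why unsupervised clustering struggles on this kind of data.

On a noisy two-fiber recording, k-means (with k even fixed to the true
track count) applied to PCA features of the raw waveform is scored against
the marking-method ground truth with ARI/NMI/V-measure, across 2-8
principal components — and compared with the supervised SVM accuracy on
the same spikes.
"""

from mngsort import (
    ClassifierSpec,
    SyntheticConfig,
    extract_aligned_waveforms,
    extract_features,
    generate_recording,
    make_template_pair,
    pca_component_sweep,
    run_cv,
)

# moderately similar templates + realistic noise: a hard recording
t0, t1 = make_template_pair(0.35, fs=10000.0)
cfg = SyntheticConfig(n_fibers=2, n_sweeps=50, templates=(t0, t1),
                      noise_sd=0.5, seed=3)
waveforms, _ = extract_aligned_waveforms(generate_recording(cfg))
raw = extract_features(waveforms, "W_raw")

table = pca_component_sweep(raw, comps=range(2, 9), seed=0)
print("components  cum.var   ARI    NMI    V-measure")
for _, r in table.iterrows():
    print(f"{int(r['n_components']):>10d}  {r['cumulative_explained_variance']:.3f}"
          f"  {r['ari']:>6.3f} {r['nmi']:>6.3f} {r['v_measure']:>6.3f}")

acc = run_cv(raw, ClassifierSpec(seed=0)).accuracy
print(f"\nsupervised SVM accuracy on the same spikes: {acc:.3f}")
print("Clustering indices stay flat and low while the supervised "
      "classifier separates the fibers well — adding PCA components does "
      "not reveal hidden separability.")
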