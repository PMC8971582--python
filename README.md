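# becseg — Bose–Einstein-condensate kernel segmentation

`becseg` is a small library and command-line tool for binary segmentation of
grayscale images — the motivating use case is separating a glioma-like bright
region from the background of a brain MR slice — using a similarity kernel
borrowed from Bose–Einstein statistics inside a support-vector machine.

## The kernel and the pipeline

The Bose–Einstein occupation number `n(ε) = 1/(exp(ε/(k_B T)) − 1)` becomes a
pixel-similarity function by feeding it the shifted distance between two
feature vectors, with the Boltzmann constant replaced by its mantissa:

    G(x1, x2) = 1 / (exp(‖x1 − x2 − μ‖ / (1.38 · T)) − 1)

Two dimensionless hyperparameters remain: a temperature `T ≠ 0` and a
chemical potential `μ` that shifts the argument. The kernel is singular at
zero argument, asymmetric in its inputs when `μ ≠ 0`, and not positive
semidefinite, so `becseg` supplies the numerical repairs a standard
maximum-margin classifier needs: a denominator floor plus value cap at the
singularity, symmetrization `(K + Kᵀ)/2`, and eigenvalue clipping of the
training Gram with a consistent spectral filter on the test similarities.

Segmentation runs in five steps: rescale intensities to (0, 10), flatten the
image to a one-dimensional intensity table, bootstrap weak labels by Otsu
thresholding (or 2-means), train a precomputed-kernel SVM on a stratified
pixel subsample, and reshape the 0/1 predictions into a mask (1 = target
region). Results are scored with precision, recall and the F-measure
`F = 2PR/(P + R)`, and a sweep module tabulates P/R/F over a `T × μ` grid and
selects the max-F cell deterministically. A Gaussian kernel
`exp(−a²/(2σ²))`, default `σ = 0.125`, runs through the identical pipeline as
the baseline. A synthetic-data module generates core+annulus phantoms with
ground truth and labeled point clouds, so everything is testable offline.

## Worked example

```sh
python examples/segment_phantom.py
```

```
default  phantom: P=1.0000 R=1.0000 F=1.0000  (1556 px predicted tumor, 1556 px true)
noisy    phantom: P=0.9986 R=0.9120 F=0.9533  (1421 px predicted tumor, 1556 px true)
```

The noiseless 128×128 phantom (bright core 9, enhancing ring 6, background 1)
is recovered exactly at the reference operating point `(T, μ) = (6, 3)`; with
Gaussian pixel noise of sd 0.3 the harmonic mean of precision and recall
stays above 0.95. The other example scripts —
`examples/kernel_basics.py`, `examples/sweep_phantom.py`,
`examples/node_clustering.py` — walk through the kernel's analytic behavior,
the hyperparameter sweep, and the BEC-vs-Gaussian point-cloud comparison.

The same pipeline is available from the shell:

```sh
becseg simulate --preset noisy --out-dir phantom/
becseg segment phantom/image.png --truth phantom/truth.png \
    --t 6 --mu 3 --out mask.png
becseg sweep phantom/image.png phantom/truth.png \
    --t-grid -6:6 --mu-grid 0:6 --out sweep.csv
```

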