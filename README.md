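# entroseg

Maximum-entropy multilevel thresholding for grayscale medical-style images —
the histogram-based segmentation step used to separate liver, lesion and
background tissue on CT slices, where adjacent structures have similar gray
values and a good global threshold is not obvious by eye.

`entroseg` provides:

- the **Kapur maximum-entropy criterion** for single- and multi-level
  thresholding, with an exact **exhaustive oracle** over all threshold
  vectors;
- a **population-based (genetic) optimizer** for the same criterion, for
  problem sizes where enumeration is not wanted;
- a **synthetic CT-like liver phantom** generator with exact per-pixel ground
  truth, for validating threshold recovery;
- **Dice/Jaccard evaluation** of predicted label maps against ground truth;
- an `entroseg` **CLI** wiring the pipeline end to end with reproducibility
  manifests.

## The model

A gray image with `Z` levels has normalized histogram `q`, where `q_o` is the
fraction of pixels at level `o`.  A threshold vector `u_1 < … < u_m`
partitions the gray range into `m+1` classes, class `i` spanning
`[u_i, u_{i+1})` (sentinels `u_0 = 0`, `u_{m+1} = Z`).  With class mass
`e_i = Σ q_o` over the class's levels, the within-class entropy is

    J_i = − Σ (q_o / e_i) · log(q_o / e_i)

and the segmentation criterion is the total entropy

    J(u) = Σ_{i=0}^{m} J_i ,      u* = argmax_u J(u) ,

maximized over all feasible vectors (every class must carry nonzero mass).
The log base (2, e, 10) only rescales `J`, so `u*` is base-invariant; values
are reported in bits by default.  For `m = 1` this reduces to the classic
two-region rule: below the threshold → black, at or above → white.

## Worked example

```python
import entroseg as es

spec = es.preset("liver3", seed=0)              # 256x256, means 40/120/200, noise SD 10
image, truth = es.generate_phantom(spec)
thresholds, labels, result = es.segment(image, m=2, method="exhaustive")
print("thresholds:", thresholds.cuts)
print("objective (bits):", round(result.best_value, 4))
report = es.evaluate(labels, truth)
print("per-class Dice:", [round(d, 4) for d in report.per_class_dice])
```

prints

```
thresholds: (98, 139)
objective (bits): 16.1332
per-class Dice: [0.9919, 0.977, 0.9774]
```

The two recovered cuts fall strictly between the class means (40 < 98 < 120 <
139 < 200), so background, liver and tumor are each recovered with Dice above
0.97.  The cuts sit below the midpoints of the means — the entropy criterion
places them where within-class entropies balance, not at the histogram
valleys — which is exactly the behavior the exhaustive oracle and the
evaluation module make visible.

The same run from the shell:

```bash
entroseg phantom --preset liver3 --seed 0 --out-dir out/ph
entroseg segment --input out/ph/phantom.png --m 2 --method exhaustive --out-dir out/seg
entroseg evaluate --pred out/seg/labels.png --truth out/ph/truth.png --out out/eval.json
```

Each output directory contains a `manifest.json` (resolved parameters, seed,
input digests, tool version) sufficient to reproduce the run; seeded commands
are byte-identical across invocations.

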