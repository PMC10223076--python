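# earcount

Counting wheat ears — or any dense, small, near-stationary targets — in
low-altitude survey video by **tracking-by-detection**. A per-frame detector
(e.g. a YOLO-family model) emits bounding boxes; `earcount` links them into
identity-preserving tracks and estimates abundance as the number of distinct
confirmed track IDs over the video. Static-image counting double-counts ears
seen in overlapping frames; unique-ID counting does not.

The package is aimed at plant-phenotyping practitioners who already have a
detector and need the association, counting, and evaluation machinery —
plus a synthetic scene simulator so the whole pipeline can be tested at desk
scale, without any imagery.

## The method

Each track carries an 8-dimensional constant-velocity Kalman state

x = (μ, ν, γ, h, μ̇, ν̇, γ̇, ḣ)

where (μ, ν) is the box center, γ = w/h the aspect ratio, and h the box
height in pixels. Per frame, every track is predicted forward and matched to
detections by a cascade (most recently updated tracks first) of gated
Hungarian assignments. A track i / detection j pair is admissible only if
both gates pass:

- **motion gate** — squared Mahalanobis distance
  d⁽¹⁾(i,j) = (dⱼ − yᵢ)ᵀ Sᵢ⁻¹ (dⱼ − yᵢ) ≤ 9.4877 (χ²₀.₉₅, 4 dof), with yᵢ
  the projected state mean and Sᵢ the innovation covariance;
- **appearance gate** — minimum cosine distance
  d⁽²⁾(i,j) = min_k (1 − rⱼᵀ r_k) over the track's gallery of up to 100
  past unit-norm re-identification embeddings, thresholded at
  `MAX_DIST = 0.3`.

The assignment cost is C(i,j) = λ·d⁽¹⁾ + (1−λ)·d⁽²⁾ (default λ = 0:
appearance-driven cost, motion as a gate — the right regime for a moving
camera). Unconfirmed tracks and just-missed leftovers fall back to IoU
matching (`MAX_IOU_DISTANCE = 0.8`). New tracks confirm after
`N_INIT = 5` consecutive hits, which filters transient false positives out
of the count; detections are pre-filtered at `MIN_CONFIDENCE = 0.2` and
NMS overlap 0.5.

Also included, as standalone array operators: the three attention blocks
used to strengthen the detector backbone (global-context Gram-matrix
fusion, omni-dimensional dynamic convolution, coordinate attention), the
residual ReID network architecture (3×128×64 crop → 512-dim unit feature)
with its exact layer-shape trace, and the evaluation suite (precision /
recall, all-point-interpolated AP and mAP, count-based MOTA with ID
switches, per-video counting L1 and accuracy).

## Worked example

```python
import earcount as ec

# simulate a survey pass: 80 identities, 200 frames, 640x640 viewport
# moving 6 px/frame, 5% misses, 5% false positives, 2 px jitter
cfg = ec.SceneConfig(n_identities=80, n_frames=200, seed=7)
truth = ec.generate_scene(cfg)
detections = ec.corrupt_to_detections(truth)

history, tracker = ec.run_tracker(detections, ec.TrackerConfig())
report = ec.count_report(len(tracker.confirmed_ids), truth.total_identities)
print(truth.total_identities, report.predicted_count,
      report.l1_loss, report.accuracy_percent)
```

prints

```
80 80 0 100.0
```

— all 80 simulated identities were recovered as exactly 80 confirmed track
IDs (L1 error 0, accuracy 100.0%). Under the same corruption at 300
identities a typical run gives `298 297 1 99.7`: one short-lived identity
never accumulated the 5 consecutive hits needed to confirm.

The same pipeline is scriptable from the shell:

```bash
earcount simulate --out bench/ --seed 7
earcount track --det bench/det.txt --emb bench/det.emb --out bench/tracks.txt
earcount count --tracks bench/tracks.txt --truth 80
earcount evaluate --gt bench/gt.txt --hyp bench/tracks.txt
```

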