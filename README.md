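# gaitpose

Markerless sagittal-plane gait analysis from monocular RGB video, aimed at
rehabilitation settings (e.g. patients walking with a lower-limb
exoskeleton) where contact sensors disturb the very gait being measured.

The package implements a complete pose-to-gait pipeline:

1. **Label codec** — an 8-joint skeleton (shoulders, hips, knees, ankles)
   is encoded as four training-target grids at 1/4 input resolution:
   per-joint Gaussian **heatmaps** `H(p) = exp(-‖p - p₀‖² / 2σ²)` (σ = 6),
   sub-stride **offset** maps `O = (x - 4⌊x/4⌋)/4` written on the
   positive-sample disc `‖p - p₀‖² ≤ d_th` (d_th = 36), binary
   **limb-guidance** masks marking the pixels of each of the 8 bone
   connections (trunk half-width δ = 8 px), and a full-resolution relative
   **depth** map. Decoding is argmax + offset and is exact to quarter-pixel
   precision.
2. **Pose network** — a compact multi-branch CNN (lossless Focus
   space-to-depth stem, SE-ResNeXt stages, FPN fusion) emitting the four
   branches above; depth and limb-guidance are *implicit supervision*:
   they shape training gradients but only heatmap + offset are used to
   regress joints at inference. Full and Lite width presets differ ~4× in
   parameter count. The tensor engine (autograd, grouped conv2d, Adam) is
   a self-contained numpy implementation.
3. **Training** — multi-task MSE loss
   `L = (1/mn) Σ [αL_heat + βL_jgs + L_depth] + (γ/lk) Σ L_off`
   with α, β, γ = 16, 4, 2, offset errors restricted to positive cells;
   occlusion / ±10° rotation / mirror augmentation; 4:1 random splits;
   pretrain/fine-tune schedules with partial backbone freezing and a
   grayscale-luminance depth proxy for RGB-only data.
4. **Gait analysis** — closed-form post-processing of per-frame keypoints
   with camera focal lengths and leg-segment lengths: hip angle
   `arccos(f_x Δy / √(f_y²Δx² + f_x²Δy²))` (thigh vs. vertical-down,
   depth cancels), knee flexion from the thigh/calf vector dot product,
   heel-strike/toe-off detection from ankle forward displacement, stride
   length `D_sl = (l₁′ sin θ′ + l₂′ sin φ′) − (l₁ sin θ + l₂ sin φ)`,
   stride cycle and speed, and the phase symmetry index
   `D_ps = √(T₀/T) · (0.62·min/max(ST) + 0.38·min/max(SW))`
   (T₀ = 1.2 s; 1 = perfectly symmetric, normatively timed gait).
5. **Evaluation** — PCKs (errors normalized by the smaller side of the
   truth-keypoint bounding box, thresholds 0.1 / 0.08) and a
   `√SSE / F` joint-angle curve-similarity score.
6. **Synthetic walker** — a stick-figure generator with closed-form
   kinematics (hip −10°…40°, knee 0°…67° by default), rendered RGB frames
   with aligned relative-depth maps and exact keypoint ground truth, so
   the entire pipeline is testable without recorded data.

## Worked example

```python
import json
from gaitpose import (WalkerParams, simulate_gait, render_frames,
                      LegLengths, gait_report)

p = WalkerParams(image_size=256, seed=11)          # symmetric 1.2 s gait
traj = simulate_gait(p, duration_s=6.0)            # closed-form kinematics
frames, depths, kps = render_frames(traj, p)       # stick-figure video
legs = LegLengths(l1=p.thigh_l, l2=p.calf_l, l1p=p.thigh_r, l2p=p.calf_r)
rep = gait_report(kps, p.camera, legs, p.fps)
print(json.dumps(rep.to_dict(), indent=1))
```

prints

```json
{
 "stride_length_m": 0.5569783723578536,
 "cycle_time_s": 1.2,
 "speed_m_s": 0.46414864363154473,
 "phase_symmetry": 0.9999999999999998,
 "short_cycle_flag": false
}
```

The walker strides 0.56 m every 1.2 s cycle (0.46 m/s), and because its
left and right stance/swing times are identical at the normative cycle
time, the phase symmetry index is 1 — the healthy-gait reference value
(clinically, values above 0.9 are considered normal). Recovered joint
ranges match the generator: hip −7.98°…35.0°, knee 0°…59.9°, inside the
normal walking ranges of motion.

The same pipeline is scriptable from the shell:

```sh
gaitpose simulate --n 200 --out data/
gaitpose train --config cfg.yml --data data/ --out model.npz
gaitpose infer --ckpt model.npz --data data/ --out pred.json
gaitpose eval  --pred pred.json --truth truth.json --eps 0.1,0.08
gaitpose gait  --poses pred.json --subject subject.yml --out report.json
```

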