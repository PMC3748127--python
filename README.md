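# myomri

Noninvasive muscle phenotyping of the mouse hindlimb, as used to characterize
nemaline-myopathy models such as the Tg(ACTA1)^Asp286Gly^ mouse: quantitative
muscle MRI (3-point Dixon fat–water imaging, multi-echo T2 mapping, diffusion
tensor imaging), dynamic ³¹P magnetic resonance spectroscopy of energy
metabolism, and electrically evoked force recordings — implemented as a
tested, reusable pipeline with a digital hindlimb phantom standing in for
raw scanner and ergometer data.

The package is aimed at small-animal imaging groups who want the full
acquisition-to-table analysis chain (and its validation machinery) without
vendor or in-house IDL tooling.

## What it computes

**Dixon fat–water separation.** Three gradient echoes with water/fat in
phase, opposed, and in phase again give
S₁ = (W+F)e^{iφ₁}, S₂ = (W−F)e^{iφ₂}, S₃ = (W+F)e^{iφ₃}. The field phase is
estimated as φ = arg(S₁*S₃)/2, the opposed echo demodulated, and
W = (|S₁|+S₂ᶜ)/2, F = (|S₁|−S₂ᶜ)/2. Fat percentage per voxel is
100·F/(F+W), averaged over the muscle mask of the four largest slices.
Maximal cross-sectional area (CSA) comes from the largest slice of the water
image; hindlimb volume sums the four consecutive largest CSAs × 1 mm.

**T2 mapping.** Pixel-wise ordinary least squares of
log S(TE) = log S₀ − TE/T2 over the echo train (TE = 8…24 ms), with ROI
averages over the three largest slices of the posterior compartment.

**DTI.** Linear least squares on ln(S_i/S₀) = −b gᵢᵀDgᵢ (b = 0 and
450 s/mm², 12 directions), then eigenvalues λ₁ ≥ λ₂ ≥ λ₃,
ADC = (λ₁+λ₂+λ₃)/3 and FA = √(3/2)·√Σ(λᵢ−ADC)²/√Σλᵢ².

**Dynamic ³¹P-MRS.** FIDs from a rest/stimulation/recovery protocol are
summed into 18 bins (64 rest; 6×32 stimulation; 7×32 + 3×64 + 1×96
recovery at TR 1.875 s), each fitted in the time domain by constrained
nonlinear least squares on a sum of damped sinusoids with multiplet prior
knowledge (ATP doublets 1:1, β-ATP triplet 1:2:1, J = 16.5 Hz). Outputs:
PCr and Pi time courses (% of rest), intracellular pH from the Pi–PCr shift
via pH = 6.75 + log₁₀((δ−3.27)/(5.69−δ)), resting PCr/ATP from the fully
relaxed spectrum, and τPCr from a monoexponential recovery fit.

**Force analysis.** Per-train peak force, maximum dF/dt (Savitzky–Golay
derivative), half-relaxation time; Hill force–frequency fit
F(f) = F_max·fⁿ/(fⁿ+f50ⁿ); 6-min 1.7 Hz fatigue protocol binned every 15 s;
specific force (mN/mm³) by volume normalization.

**Cohort statistics.** Mean ± SEM, integer percent differences, unpaired
Student t-tests and Pearson correlations over tidy per-animal tables.

## Worked example

```python
from myomri.phantom import (mouse_hindlimb_spec, build_phantom,
                            simulate_dixon, simulate_multiecho_t2)
from myomri import dixon, relaxometry
from myomri.phantom import POSTERIOR_LABEL

gt = build_phantom(mouse_hindlimb_spec("Tg", rng_seed=1))
fw = dixon.separate_fat_water(simulate_dixon(gt, noise_sigma=0.005, rng_seed=1))
anat = dixon.measure_anatomy(fw.water_map, gt.voxel_dims_mm, n_slices=4)
print(round(anat.max_csa_mm2, 1), round(anat.volume_mm3, 1))
print(round(dixon.fat_percentage(fw, anat.muscle_mask, n_slices=4), 3))

echoes = simulate_multiecho_t2(gt, noise_sigma=0.01, rng_seed=1)
t2 = relaxometry.fit_t2_map(echoes)
print(round(relaxometry.roi_mean_t2(t2, gt.mask(POSTERIOR_LABEL)), 2))
```

prints

```
37.2 107.1
0.193
19.81
```

i.e. the transgenic phantom's maximal CSA (37.2 mm²) and 4-slice hindlimb
volume (107.1 mm³), the recovered intramuscular fat percentage (truth
0.19 %), and the posterior-ROI mean T2 (truth 19.8 ms) at SNR 100.

A CLI mirrors the library: `myomri simulate --group Tg --seed 1 --out d/`,
then `myomri dixon|t2map|dti|mrs|force` on the generated files.

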