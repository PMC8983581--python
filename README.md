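# punctaquant

Quantitative analysis of nuclear biomolecular condensates from two-channel
confocal microscopy, built for studies of phase-separating fusion
oncoproteins (e.g. NUP98 fusions such as NUP98–HOXA9) that form submicron
nuclear puncta. The package covers the full measurement chain:

- **3-D segmentation** — nuclei from the DNA (Hoechst) channel, puncta from
  the protein (mEGFP) channel via multi-scale Laplacian-of-Gaussian
  filtering, thresholding, and seeded watershed with half-maximum boundary
  refinement;
- **per-cell condensate metrics** — puncta number density (per 10³ μm³
  nuclear volume), mean punctum volume *V*ₚ, light- and dense-phase levels
  [LP] and [DP], partition coefficient *K*ₚ = [DP]/[LP], Gibbs free energy
  of transfer ΔG_Tr = −RT ln *K*ₚ, Pearson colocalization with the DNA
  channel, and nuclear-periphery statistics;
- **FRAP analysis** — background/reference normalization and
  single-exponential recovery fits, I(t) = I₀ + A·(1 − 2^(−t/T₁/₂)),
  reporting the half-time T₁/₂ and mobile fraction M_f = A/(1 − I₀);
- **in vitro assays** — maximum-intensity projections, condensate counting
  in dilution series, saturation-concentration (C_sat) bracketing, and
  background-subtracted turbidity (A340) summaries;
- **FG-motif valence accounting** — FG/GLFG motif counting over annotated
  regions, F→A and FG→AA mutation application, residue-composition
  profiles;
- **a ground-truthed synthetic-data generator** — ellipsoidal nuclei with
  chromatin-like DNA texture, non-overlapping spherical puncta of known
  dense/light intensity ratio, PSF blur, Poisson + Gaussian noise, FRAP
  traces and dilution ladders — so every stage is testable by parameter
  recovery.

## Worked example

Generate a synthetic cell (80 puncta, true *K*ₚ = 10, realistic noise) and
quantify it:

```bash
punctaquant simulate --seed 4 --out scene.ome.tif
# wrote scene.ome.tif (80 puncta, nucleus 119.4 um^3)

punctaquant quantify scene.ome.tif --psf-sigma 0.25 0.1 0.1 --outdir results
# 79 puncta in 1 cells -> results
```

`results/cells.csv` then contains one row per nucleus:

| quantity | value | meaning |
|---|---|---|
| `puncta_count` | 79 | detected puncta (80 seeded) |
| `puncta_density` | 738.9 | count per 10³ μm³ nuclear volume |
| `v_p` | 0.0898 | mean punctum volume, μm³ (true sphere volume ≈ 0.113) |
| `k_p` | 9.60 | partition coefficient (true value 10) |
| `delta_g_tr` | −1.394 | kcal/mol at 310.15 K; negative = partitioning favorable |

The same functions are importable as a library:

```python
from punctaquant import SceneParams, generate_cell_stack
from punctaquant.pipeline import RunConfig, analyze_stack

params = SceneParams(puncta_count=50, kp_true=10.0, seed=7)
stack, truth = generate_cell_stack(params)
nuclei, puncta, cells = analyze_stack(stack, RunConfig(psf_sigma_um=params.psf_sigma))
print(cells[0].k_p)          # ≈ truth.kp_true
```

Other subcommands: `segment` (nucleus table), `frap` (fit a recovery
trace), `invitro` (C_sat bracket from a dilution manifest), `seq` (FG
valence with optional mutation spec), `report` (full multi-construct run
from a YAML config, with group statistics).

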