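# sipaug

Analytics for **bioaugmentation microcosm experiments**: sediment dosed with
the sulfonamide antibiotic sulfamethoxazole (SMX) and inoculated with an
exogenous degrader strain, tracked through chemistry (SMX time series), 16S
amplicon community profiles, and DNA stable-isotope probing (DNA-SIP). The
package is written for microbial ecologists who have — or want to prototype
against — the standard products of such a study, and it ships a synthetic
experiment generator so every analysis stage is testable end to end without
sequencing data.

Four inference stages sit behind one importable API:

* **Kinetics** — per-treatment, per-dosing-phase removal efficiency
  `100·(C_start − C_end)/C_start` and first-order rates from the ln-linear
  fit `ln C = ln C₀ − k·t` (half-life ln2/k, R², LOQ handling).
* **Community statistics** — observed features, Shannon H = −Σ p·ln p,
  Pielou evenness H/ln S; CLR transform `log(x/g(x))` with Dirichlet
  Monte-Carlo + Wilcoxon + Benjamini–Hochberg differential abundance;
  Bray-Curtis and normalized weighted UniFrac
  Σ_b ℓ_b|p_A − p_B| / Σ_b ℓ_b(p_A + p_B); PCoA; PERMANOVA with
  permutation p = (1 + #{F* ≥ F})/(1 + n_perm).
* **Co-occurrence networks** — Pearson |ρ| > 0.6 edges per treatment,
  greedy-modularity modules, within/among-module connectivity (Zi, Pi) with
  the 2.5/0.62 role thresholds (network hub / module hub / connector /
  peripheral), and structural robustness by natural connectivity
  λ̄ = ln((1/N)Σ e^{λᵢ}) under random vs targeted keystone removal,
  including the equivalent-random-loss statistic.
* **DNA-SIP** — qPCR-weighted abundance profiles along 12-fraction CsCl
  gradients, heavy-fraction designation, and a three-part conjunctive rule
  (heavy enrichment ratio ≥ 2, buoyant-density center-of-mass shift
  ≥ 0.004 g/mL, heavy abundance ≥ 0.5 %) calling ¹³C-labelled taxa from a
  paired labelled/control gradient.

The generator plants known structure — calibrated degradation rates, an
inoculant that washes out when SMX is depleted, responders coupled to the
degraded fraction, guild-correlated abundance blocks, and labelled taxa
whose DNA shifts by `AFE × 0.036 g/mL` on the Schildkraut baseline
BD = 1.660 + 0.098·GC — so each stage can be validated against ground
truth. See `docs/methods.md` for the full model description.

## Worked example

`examples/` holds one short script per capability. Degradation kinetics
(`python examples/01_degradation_kinetics.py`):

```
 treatment phase  removal_pct  removal_sd  k_per_day  half_life_days  removal_vs_ref_abs_pts
 Paen.Inoc     I      100.000       0.000     12.107           0.057                  93.084
 Pseu.Inoc     I       81.087       0.680      0.212           3.269                  74.171
  non-Inoc     I        6.916       6.260      0.011          61.922                   0.000
sterilized     I        3.497       3.176      0.001         564.675                  -3.419
...
```

Each row is one treatment in one dosing phase: the sterilized control loses
<3.5 % of SMX in 8 days (abiotic only), the non-inoculated sediment ~10 %
(here 6.9 ± 6.3 % under 5 % measurement noise), while the inoculated systems
remove 81–100 % — about 70 percentage points above the non-inoculated
control (`removal_vs_ref_abs_pts`).

DNA-SIP calling (`python examples/04_dna_sip.py`), on a gradient pair with
five planted labelled degraders:

```
        heavy_mean_labeled  heavy_mean_control  enrichment_ratio  delta_center_of_mass  rank
ASV059              0.0301              0.0006           45.9082                0.0263     1
ASV017              0.0282              0.0011           23.5105                0.0193     2
...
5/5 planted degraders recovered, 0 false positives.
```

`heavy_mean_*` are qPCR-weighted relative abundances in the ≥1.720 g/mL
fractions; a positive `delta_center_of_mass` means the taxon's whole
gradient profile moved toward heavier DNA — the signature of ¹³C
assimilation.

The same workflow is available from the shell:

```bash
sipaug all --seed 1 --outdir out/demo       # simulate + every stage
sipaug sip --labeled out/demo/sip_Paen_Inoc_13C.tsv \
           --control out/demo/sip_Paen_Inoc_12C.tsv --out calls.tsv
```

All outputs are plain TSV/CSV/newick with documented headers, plus a
`manifest.json` carrying the configuration echo and SHA-256 digests —
rerunning with the same seed reproduces the files bit for bit.

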