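# aidcycle

Cell-cycle-resolved quantification of AID nuclear stability and single-cell
Ig VH somatic-hypermutation analysis, with a synthetic single-cell data
generator that provides ground truth for every stage.

## Background

Activation-induced deaminase (AID) initiates somatic hypermutation and
class-switch recombination of immunoglobulin genes in B cells, but it is also
genotoxic, and cells restrain it by keeping most of the protein cytoplasmic
and by degrading the nuclear fraction. Both the nuclear export (blocked by
leptomycin B, LMB) and nuclear proteasomal degradation (blocked by MG132)
arms of this control can be probed with drug time courses in high-content
screening (HCS) microscopy, where per-cell compartment signals are measured
for thousands of cells and cell-cycle phase can be read out from each cell's
total DNA (DAPI) content. Because nuclear AID mutates the Ig loci, the
stability of nuclear AID across the cell cycle connects directly to the
mutation spectra recovered from single-cell VH amplicons and to functional
readouts such as surface-IgM loss.

`aidcycle` implements that analysis chain as a reusable library:

| Module | What it does |
| --- | --- |
| `aidcycle.simulate` | Synthetic data: two-compartment shuttling ODE with phase-specific nuclear degradation and drug blockades; an HCS measurement model (bleed-through + noise + per-phase areas/DAPI); VH mutant sequences from a substitution spectrum; sIgM staining mixtures |
| `aidcycle.hcs` | Per-cell quantification: compartment averages, two-sided signal gating against a mock control, phase assignment by DNA-content rank, bleed-through baseline regression and nuclear-signal correction, population summaries |
| `aidcycle.kinetics` | Fold-change time courses vs untreated, curve-shape classification, 1–2 hr degradation slopes, per-phase rates relative to G1 with Welch tests |
| `aidcycle.shm` | VH mutation calling by global alignment, spectrum deduplication, subset-order genealogies, substitution-spectrum and mutation-load tabulation, χ² comparisons, sIgM loss frequencies |
| `aidcycle.io`, `aidcycle.config`, `aidcycle.pipeline`, `aidcycle.cli` | File formats, seeded run configuration, end-to-end orchestration, thin command-line interface |

All randomness in a run flows from a single seed; identical configurations
give byte-identical numeric outputs.

## Worked example

Simulate a four-arm drug time course, quantify it, and look at the treatment
kinetics (this is `examples/02_treatment_kinetics.py`):

```python
from aidcycle import kinetics, pipeline

cells, mock = pipeline.simulate_hcs_experiment(n_cells=2000, n_mock=2000, seed=1)
quantified, report, fit = pipeline.quantify_cells(cells, mock)

nuclear = pipeline.treatment_fold_curves(quantified, value="nuclear_avg")
for treatment, curve in sorted(nuclear.items()):
    res = kinetics.characterize_curve(curve)
    print(
        f"nuclear {treatment:>9}: {res['shape']:<12} "
        f"peak {res['peak_fold']:.2f} at {res['peak_time']:g} hr, "
        f"terminal {res['terminal_fold']:.2f}"
    )

cyto = pipeline.treatment_fold_curves(quantified, value="cyto_avg")
print(f"cytoplasmic LMB terminal fold: "
      f"{kinetics.characterize_curve(cyto['LMB'])['terminal_fold']:.2f}")

_slopes, ratios = pipeline.rate_ratio_experiment(seed=2)
print()
print(ratios.round(4).to_string(index=False))
```

Output:

```
nuclear       LMB: flat         peak 1.04 at 1 hr, terminal 0.94
nuclear LMB+MG132: rise-plateau peak 1.71 at 4 hr, terminal 1.71
nuclear     MG132: flat         peak 1.07 at 4 hr, terminal 1.07
cytoplasmic LMB terminal fold: 0.47

phase  ratio_mean  ratio_sem  n  p_vs_G1
   G1      1.0000     0.0000  4      NaN
  G2M      1.5202     0.0190  4   0.0001
    S      1.5502     0.0443  4   0.0011
```

Blocking export and nuclear degradation together (LMB+MG132) accumulates
nuclear signal to a ~1.7-fold plateau while the cytoplasmic signal under
export blockade roughly halves by 4 hr, and the recovered per-phase
degradation rates are ~1.5-fold faster in S and G2/M than in G1 — the
generator's configured truth (1.56 and 1.54) recovered within a few percent,
with Welch p < 0.05.

The hypermutation stage (`examples/03_vh_hypermutation.py`) simulates VH
amplicons, calls mutations back against the reference, and summarizes:

```
sequences: 400  failed amplicons: 0
distinct mutation spectra: 77
point mutations: 138  deletions: 1  insertions: 0
marginals: A/T 15.2%  G/C 84.8%  G->T 0.0%
mutations per sequence: {0: 320, 1: 42, 2: 24, 3: 11, 4: 0, 5: 3}
CDT1 vs untagged load distribution: chi2 = 669.3, df = 3, p = 9.42e-145
genealogy: 77 nodes, 1 ambiguous parent(s)
```

More narrative scripts live in `examples/`:

* `01_simulate_and_quantify.py` — simulation, gating, phase assignment, baseline fit
* `02_treatment_kinetics.py` — fold curves, curve shapes, rate ratios
* `03_vh_hypermutation.py` — mutation calling, spectra, genealogies, χ²
* `04_sigm_loss.py` — surface-IgM loss frequency estimation

## Command line

```sh
aidcycle run --seed 1 --out out/            # every stage end to end
aidcycle simulate --kind hcs --seed 1 --out out/
aidcycle quantify --cells out/cells.csv --mock out/mock.csv --out out/
aidcycle shm-call --reads out/shm_AID-mCherry.fasta --out out/
```

`--config cfg.yaml` accepts a YAML `RunConfig`; exit codes are 0 (success),
2 (configuration error), 3 (data error).

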