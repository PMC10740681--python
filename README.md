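# rotifd

Trait-based analysis of how a trophic gradient restructures a zooplankton
community: a composite trophic level index (TLIc), categorical functional
groups, distance-based functional diversity (FRic / FEve / FDiv), and
beta-diversity partitioning into replacement and richness-difference
components — driven by a synthetic community generator so the whole
pipeline is testable without any field data.

## Modules

| module | what it does |
|---|---|
| `rotifd.synthetic_community` | simulates a multi-site monthly survey: latent trophic gradient, back-solved water chemistry, categorical trait table with realistic trophi→feeding syndromes, and a community assembled by a one-sided Gaussian stress (environmental-filtering) niche model |
| `rotifd.trophic_state` | per-parameter `TLI_j = 10(a_j + b_j ln x_j)` subscores, correlation-derived weights `W_j = r_j²/Σr²`, composite TLIc, trophic-state class (oligo/meso/eutrophic at 30 and 50) |
| `rotifd.functional_traits` | fixed 7/3/4/3 modality vocabulary (trophi, size, feeding, swimming), trait-table validation, composition by modality, dominance screen `Y = (nᵢ/N)·fᵢ` |
| `rotifd.functional_diversity` | Gower / indicator Bray–Curtis trait distances, PCoA with additive (Cailliez) correction, convex-hull FRic, MST-based FEve, centroid-divergence FDiv |
| `rotifd.beta_partition` | Bray–Curtis matrices, Podani-family decomposition `D = Repl + RichDiff` (Jaccard or Ružička base), (Sim, Repl, RichDiff) triads, percent contributions, UPGMA clustering with Newick output |
| `rotifd.stats_report` | Pearson association with stars, simple regression with 95 % mean-response band, one-way ANOVA + Tukey HSD with letters, and the figure/table report bundle |

## CLI

Stages exchange canonical CSVs (UTF-8, comma, header row) through `--outdir`:

```bash
rotifd simulate --seed 1 --outdir out        # abundance/traits/environment + truth
rotifd tli      --outdir out --coeff-set canonical
rotifd traits   --outdir out                 # composition + dominance screen
rotifd fd       --outdir out                 # trait space + FRic/FEve/FDiv
rotifd beta     --outdir out --beta-family podani-jaccard
rotifd all      --seed 1 --outdir out        # everything + figures + manifest
```

Simulation knobs (`--config cfg.yaml`) include the gradient range,
filtering strength κ (0 = neutral assembly), dominance concentration θ,
noise levels and the trait vocabulary; see `rotifd.synthetic_community.SimulationConfig`.

Two TLI coefficient sets are shipped: `canonical` (the standard lake-survey
constants, default) and `as_printed` (reproduces a published variant whose
SD/COD rows appear typographically corrupted).

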