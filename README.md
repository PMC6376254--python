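# kospec

Quantification of antibody specificity from knockout-control validation
experiments.

When a new antibody is characterized against a CRISPR knockout (KO) cell
line, two questions matter: on a western blot, how much of the signal in the
control lane is the specific band — and does that band vanish in the KO
lane?  And by immunofluorescence, does the staining show the protein's
expected localization pattern, and does it fall to background in KO cells?
`kospec` turns both assessments into reproducible numbers:

* **Lane densitometry** — a fixed-width (default 20 px) vertical intensity
  profile per lane, an automated segmented-line baseline anchored in the
  valleys between bands, prominence-based peak detection, baseline-corrected
  trapezoidal peak areas, and log-linear molecular-weight calibration
  against a ladder.
* **WB specificity index** — with the band of interest defined as the band at
  the expected size (~25 kDa for the bundled panels) that disappears or
  diminishes in the KO lane,

  ```
  index = [ A(band of interest) / A(all peaks) ]_control
        − [ A(band of interest) / A(all peaks) ]_KO
  ```

  where `A` is baseline-corrected peak area.  The index lies in [−1, 1]:
  1 for a single fully specific band that is lost in KO, 0 for identical
  control/KO lanes.  Antibodies are ranked by it.
* **IF scoring** — a quantitative surrogate for visual scoring: puncta are
  found with a scale-normalized Laplacian-of-Gaussian detector, and an
  antibody is scored on two binary criteria: a *pattern* criterion (enough
  puncta per cell, enough of the above-background signal inside puncta,
  punctum density in the perinuclear annulus clearly above the rest of the
  cytoplasm) and a *KO-loss* criterion,
  `(mean_KO − mean_sec) / (mean_WT − mean_sec) ≤ 0.25`, referenced to the
  secondary-only control.
* **Synthetic data with exact ground truth** — multi-lane blots (Gaussian
  bands with closed-form areas, polynomial background, Gaussian/Poisson
  noise) and IF fields (cells, nuclei, placed puncta), so every stage of the
  pipeline is testable without real images.

## Worked example

```bash
kospec full-demo --outdir demo --seed 1 --replicates 5
```

simulates an 8-antibody validation panel (four "monoclonal", four
"polyclonal", with known ground-truth signal fractions), quantifies every
control/KO lane pair, ranks the antibodies, repeats the ranking under five
independent noise realizations, and scores the 2×2 immunofluorescence
phenotype panel.  It prints:

```
 rank antibody_id  fraction_control  fraction_ko  index  tied flags
    1       mAb-1            0.8985       0.0000 0.8985 False
    2       mAb-2            0.8201       0.0000 0.8201 False
    3       mAb-3            0.7399       0.0393 0.7006 False
    4       mAb-4            0.6607       0.0595 0.6012 False
    5       pAb-1            0.5801       0.0799 0.5001 False
    6       pAb-2            0.5002       0.1007 0.3995 False
    7       pAb-3            0.4201       0.1199 0.3002 False
    8       pAb-4            0.3387       0.1433 0.1954 False
      antibody_id pattern ko_loss  n_puncta_per_cell  puncta_signal_fraction  perinuclear_enrichment  ko_loss_ratio     flags
    punctate_lost       +       +               47.0                     1.0                   4.905         0.0008
     diffuse_lost       -       +                0.0                     0.0                     NaN         0.0033 no puncta
punctate_retained       +       -               48.4                     1.0                   5.123         1.0012
 diffuse_retained       -       -                0.0                     0.0                     NaN         1.0002 no puncta
rank stability: 5/5 replicates identical
```

The measured indices track the generator's true values (0.90, 0.80, …,
0.20) to within a few hundredths at a band signal-to-noise ratio of 20, the
ranking is identical in every replicate, and only the punctate phenotypes
pass the pattern criterion while only the KO-lost phenotypes pass the
KO-loss criterion.  `demo/` also receives per-lane peak tables
(`peaks.csv`), the ranking bar chart (`ranking.png`), the IF score table and
a `resolved_config.yaml` provenance copy.

Other subcommands: `simulate-blot` / `simulate-if` write synthetic TIFFs,
masks and ground-truth CSVs; `quantify-blot` and `score-if` run on image
files described by a YAML config (schema documented in
`src/kospec/config.py`).

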