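# dfi — a molecular map of drug–food interactions

`dfi` is a systems-chemical-biology pipeline for asking, at the level of
individual molecules, how the phytochemicals in plant-based foods interfere
with medicines. It is aimed at computational chemical biologists and
pharmacology bioinformaticians who have (or simulate) four kinds of data:
food→compound composition tables, compound→protein bioassay measurements,
drug→protein annotations with protein categories (drug target, enzyme,
transporter, carrier), and gene-expression matrices with reference
perturbation rank profiles.

## What it computes

**Bioactivity calls.** Raw bioassay measurements are flagged positive per
endpoint — pchembl > 6 for K_i/K_d/IC50/EC50, inhibition > 30 %, potency
< 50 µM — and replicated measurements of one (compound, protein) pair are
summarized by their positive-measurement frequency; pairs with frequency
> 0.5 become *confident interactions* with a geometric-mean representative
affinity. A food compound is then *active* against a protein when its
affinity is at least as potent as the weakest drug binding that protein
(the drug activity range), falling back to the category-level mean drug
affinity when no drug binds the protein.

**Chemical space.** Each compound gets a 1029-column descriptor vector
(1024-bit Morgan circular fingerprint, radius 2, plus TPSA, SlogP, MW and
Lipinski HBA/HBD), supporting PCA of the library and similarity matching:
exact structure matches first, otherwise Tanimoto TC ≥ 0.85 with |ΔMW| <
50 g/mol. Matched reference compounds donate their confident protein
targets; targets of exactly matched compounds are further expanded through
protein–protein-interaction neighbors with confidence score > 400, and
rodent proteins are mapped to human orthologs.

**Networks.** Foods are linked by the number of shared interacting
proteins; drug targets of one disease class are linked when ≥ 3 (drug,
food) pairs are active against both; each protein node is annotated with
its strongest-binding phytochemical (minimum nM affinity) in either the
pharmacodynamics (drug-target) or pharmacokinetics (enzyme/transporter/
carrier) context. Biological-system overrepresentation uses
exp = (tpc / tdt) · tpa.

**Expression connectivity.** Differential expression is called with a
moderated t-test (empirical-Bayes variance shrinkage) at FDR 0.05; the
significant genes form up/down *tag lists* that are scored against
reference rank profiles with a two-sided Kolmogorov–Smirnov enrichment
statistic, max-scaled to [−1, 1] across instances. A food–drug connection
is (anti-)correlated only when |ES| > 0.75, permutation p < 0.01 and the
non-null percentage exceeds 80.

## A worked example

```bash
python examples/case_studies.py
```

prints (abridged):

```
protein                      ctx  phytochemical            affinity  foods
aromatase                    pd   naringenin                 2.9 nM  beansprout, guava, licorice
aromatase                    pk   naringenin              1000.0 nM  beansprout, guava, licorice
D(2) dopamine receptor       pd   aporphine                527.0 nM  poppy-seed
ribosyl-dihydronicotinamide dehydrogenase pk resveratrol   450.0 nM  grape
```

Each row labels a protein node of the tripartite drug–target–food network
with the most potent active phytochemical against it: naringenin binds
aromatase at 2.9 nM — more potently than the anticancer drugs targeting
the same enzyme — and reaches the diet through licorice, beansprout or
guava, so those foods can plausibly interfere with aromatase-inhibitor
therapy (a pharmacodynamics, `pd`, interaction) and with drugs aromatase
metabolizes (`pk`). The other `examples/` scripts walk the synthetic
chemistry world, the descriptor/similarity machinery, the enrichment
formula and the expression-connectivity arm, each printing the numbers it
computes and what they mean.

The same stages are scriptable from the shell:

```bash
dfi simulate --profile all --seed 1 --out data/
dfi run-all --input-dir data/ --out results/
dfi connectivity --tags tags.tsv --reference reference_ranks.tsv --out conn.tsv
```

## Layout

- `src/dfi/` — the library: `io`/`records`/`config` (tables, domain types),
  `bioactivity`, `chemspace`, `networks`, `expression`, `synth` +
  `fixture` (generators with planted ground truth), `pipeline` + `cli`.
- `examples/` — narrative scripts, one per capability.
- `docs/methods.md` — model assumptions, parameter defaults, numerical
  choices and limitations.
- `tests/` — unit, property and end-to-end scientific checks.
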