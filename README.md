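# neoforge

Desk-scale neoantigen discovery: from annotated somatic variants to a
ranked shortlist of candidate tumour epitopes and multi-epitope vaccine
constructs, driven entirely by synthetic fixtures with known ground truth.

Tumour-specific peptides (neoantigens) arise when somatic alterations —
missense SNVs, frameshift indels, gene fusions, or variants in non-coding
regions — produce protein sequence absent from normal tissue. Presented by
MHC class I (8–11-mers, CD8+ T cells) or class II (15–18-mers, CD4+ T
cells), they are prime targets for personalised cancer vaccines. The hard
part is selection: most predicted binders are not immunogenic, so evidence
from several omics layers has to be combined.

`neoforge` implements the bespoke computational stages of such a workflow
as a tested Python library with a thin CLI:

* **variants** — mutant protein construction per origin class (direct
  substitution for missense; re-translation of the shifted reading frame
  for frameshifts; junction translation for fusions; six-frame translation
  of ±100 bp windows for non-coding variants, with stop codons as cleavage
  points and mutation-devoid fragments removed), tiling into
  mutation-spanning 8–11/15–18-mers, and screening against the reference
  proteome.
* **proteodb** — per-sample target/decoy search databases (strict tryptic
  pseudo-reversed decoys that conserve length and composition) and mapping
  of post-FDR (q ≤ 0.01) MS identifications back to mutant entries.
* **filters** — the shortlisting cascade: %Rank_EL binder calls
  (SB ≤ 0.5 < WB ≤ 2 for class I; < 10 for class II), expression
  (TPM > 0), mutant-specific MS evidence, the TESLA enrichment thresholds
  (affinity < 34 nM and expression > 33 TPM), and local-alignment
  similarity > 50% to experimentally validated epitopes (Smith–Waterman,
  BLOSUM62, gap 11/1).
* **cnn** — a two-branch convolutional immunogenicity classifier over the
  encoded peptide (11×42) and MHC pseudosequence (34×42): 20-dim one-hot
  plus 22 standardized physicochemical descriptors per position, two
  global features (TAP score, %Rank_EL), Adam (lr 1e-4, weight decay
  1e-3), batch 256, 50 epochs, stratified 80/20 split. Implemented in
  plain numpy with hand-written gradients; bit-reproducible under seed.
* **vaccine** — mRNA construct assembly (cap – β-globin 5'UTR – Kozak –
  t-PA signal peptide – HIS tag – CD40L adjuvant – GPGPG – epitopes joined
  by AAY – MITD – stop – α-globin 3'UTR – poly(A)) and GGGGS-linked
  peptide vaccines, with grammar-aware parsing back to the epitope list.
* **fixtures / pipeline** — a synthetic input bundle generator whose score
  tables straddle every decision boundary and whose manifest records which
  candidates must survive each stage, plus an in-process orchestrator.

## Worked example

```python
from neoforge import generate_fixture_bundle, RunConfig, run_pipeline

bundle = generate_fixture_bundle(seed=7, scale="tiny", out_dir="fixtures")
cfg = RunConfig(
    genome=str(bundle.paths["genome"]),
    transcripts_fa=str(bundle.paths["transcripts_fa"]),
    transcripts_tsv=str(bundle.paths["transcripts_tsv"]),
    proteome=str(bundle.paths["proteome"]),
    variants=str(bundle.paths["variants"]),
    fusions=str(bundle.paths["fusions"]),
    binding=str(bundle.paths["binding"]),
    presentation=str(bundle.paths["presentation"]),
    expression=str(bundle.paths["expression"]),
    ms=str(bundle.paths["ms"]),
    positive_db=str(bundle.paths["positive_db"]),
    pseudosequences=str(bundle.paths["pseudosequences"]),
    out_dir="run",
)
report = run_pipeline(cfg)
for stage in report["cascade"]:
    print(stage)
```

prints the per-stage funnel on the tiny bundle (26 mutant records, 1,083
class I + 1,297 class II candidates joined with two class I alleles):

```
{'stage': 'binding',    'n_in': 3463, 'n_out': 1769}
{'stage': 'expression', 'n_in': 1769, 'n_out': 827}
{'stage': 'ms',         'n_in': 827,  'n_out': 103}
{'stage': 'tesla',      'n_in': 103,  'n_out': 89}
{'stage': 'similarity', 'n_in': 89,   'n_out': 89}
{'stage': 'cnn',        'n_in': 89,   'n_out': 89}
```

Each count is non-increasing; the 89 surviving (peptide, allele) pairs are
exactly the bundle manifest's planted survivors — candidates from the
"golden" record engineered to be strong binders on a highly expressed
transcript with mutant-specific MS evidence and positive-database hits.
`run/neoantigens.tsv` holds the final table; every row traces back to a
variant id through `record_id`.

The same stages are available individually on the command line:
`neoforge fixtures`, `neoforge peptides`, `neoforge builddb`,
`neoforge msmatch`, `neoforge filter`, `neoforge train`, `neoforge score`,
`neoforge vaccine`, `neoforge run --config run.yaml`.

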