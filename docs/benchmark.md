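# Reproducing the full benchmark on real data

The package ships with no protein structures: the published benchmark uses
the 502-chain nonhomologous set of Cuff & Barton ("Barton502"), which must
be obtained separately, and its original random split memberships were
never published.  This recipe reproduces the pipeline end-to-end for users
who hold the data; expect results near, but not identical to, the published
numbers because the split is re-drawn.

## Prerequisites

- the Barton502 chain sequences as FASTA (`barton502.fasta`)
- classic DSSP output for every chain (`dssp/<chain>.dssp`), produced by
  running `mkdssp` on the PDB files
- a PSI-BLAST ASCII PSSM per chain (`pssm/<chain>.pssm`), produced with
  `psiblast -num_iterations 4 -evalue 1e-3 -inclusion_ethresh 2e-3
  -out_ascii_pssm <chain>.pssm` against a standard protein database
- a full AAindex1 flat file (`aaindex1.txt`) if you want the complete
  property set instead of the bundled snapshot (pass it via `--aaindex`)

## Pipeline

```sh
# 1. reproducible 336/166 split + 84-chain feature-selection subset
rsapred split --fasta barton502.fasta --split-seed 0 --out-dir splits/

# 2. labelled 11-residue segments from the DSSP annotations
rsapred extract-features --dssp dssp/ --out-dir features/

# 3. GA selection of informative properties per central residue
#    (restrict segments.tsv to the chains in splits/select.ids first;
#    full-scale settings are the defaults: population 50, r 40->10,
#    30 runs -- this is the compute-heavy step)
rsapred select-features --segments features/segments.tsv \
    --aaindex aaindex1.txt --seed 0 --out-dir selections/

# 4. train the 20 per-residue SVR models with grid refinement
#    (restrict segments.tsv to splits/train.ids first)
rsapred train --segments features/segments.tsv --selections selections/ \
    --pssm-dir pssm/ --aaindex aaindex1.txt --grid-refine \
    --out-dir model/

# 5. predict and score the held-out test chains
rsapred predict --model model/model --fasta test.fasta --pssm-dir pssm/ \
    --dssp dssp/ --out-dir predictions/
rsapred evaluate --predictions predictions/predictions.tsv --out-dir report/

# 6. hydrophobic-spine scan of highly exposed helices
rsapred spine-scan --dssp dssp/ --aed-min 90 --out-dir spines/
```

`report/evaluation.json` holds the overall and per-residue MAE plus the
Pearson correlation coefficient; `spines/spines.tsv` lists one spine call
per row with members, spacings, interruptions and the perfect flag.

The same commands run unchanged on the synthetic fixture tree written by
`rsapred synth --out-dir tree/ --seed 7`, which is how the test suite
exercises the recipe without external data.
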