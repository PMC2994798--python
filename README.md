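# panbind

Pan-specific MHC class II peptide-binding prediction. A single
feed-forward neural network covers all alleles by taking both peptide
features and the allele's MHC *pseudo sequence* (21 peptide-contact
residues) as input. Training uses a concurrent two-step procedure: in
every cycle, each training peptide's 9-mer binding core is re-identified
as the highest-scoring offset under the current weights, and one online
gradient step is then taken at that core. The released model is an
ensemble (2 encoding schemes x 10 random initializations per
cross-validation fold) whose score is the mean prediction and whose
reported binding core is the majority vote across networks.

The package also implements:

- the affinity transform `target = 1 - log(IC50) / log(15000)` and its
  inverse;
- sparse (0.9/0.05 one-hot) and BLOSUM50/5 residue encodings, flanking
  region (PFR) summaries and length features — 646 inputs per example;
- an allele distance `d = 1 - s(A,B) / sqrt(s(A,A) s(B,B))` over BLOSUM50
  scores of pseudo sequences, with nearest-neighbor lookup;
- evaluation metrics (ROC AUC with half-counted ties, Pearson r, 500 nM
  binder threshold) and three benchmark protocols: 5-fold CV,
  leave-one-allele-out, peptide-exclusion leave-one-out (inner 3-fold
  above 200 data points), and the overlapping-window ligand benchmark;
- a synthetic data generator that plants per-allele 9-mer motifs whose
  similarity tracks pseudo-sequence similarity, so the whole pipeline is
  testable offline with known ground truth.

## Command line

```bash
# generate a synthetic dataset with planted motifs (plus ligand fixtures)
panbind simulate --alleles 6 --peptides 400 --seed 1 --ligand-proteins 5 --out data/

# train a cross-validated ensemble
panbind train --data data/binding.tsv --pseudo data/pseudo.txt \
              --config cfg.yaml --out model/

# predict peptides (or scan FASTA proteins with overlapping windows)
panbind predict --model model/ --pseudo data/pseudo.txt \
                --peptides peps.txt --allele SYN-00 --out preds.tsv

# per-allele AUC / PCC of predictions against measured affinities
panbind eval --pred preds.tsv --truth data/binding.tsv --threshold 500

# allele distance matrix or nearest-neighbor lookup
panbind distance --pseudo data/pseudo.txt [--query SYN-03]

# benchmarks
panbind benchmark loo-allele  --data data/binding.tsv --pseudo data/pseudo.txt
panbind benchmark loo-peptide --data data/binding.tsv --pseudo data/pseudo.txt
panbind benchmark ligands --model model/ --pseudo data/pseudo.txt \
                          --fasta data/proteins.fasta --ligands data/ligands.tsv
```

Training configuration is a YAML file with any of: `n_cycles` (500),
`n_seeds` (10), `schemes` ([sparse, blosum]), `n_hidden` (40), `n_folds`
(5), `learning_rate` (0.1), `base` (15000), `weight_range` (0.1),
`master_seed`. Everything is deterministic given the master seed.

## Layout

- `src/panbind/data_io.py` — binding TSV / pseudo table / FASTA /
  prediction readers and writers, affinity transform
- `src/panbind/encoding.py` — residue and example encoding (646 inputs)
- `src/panbind/neuralnet.py` — feed-forward net, backprop, serialization
- `src/panbind/trainer.py` — concurrent core/weight training, overlap-
  minimizing data partitioning, ensembles, model persistence
- `src/panbind/predictor.py` — ensemble prediction, majority-vote cores
- `src/panbind/metrics.py` — AUC, PCC, per-allele evaluation
- `src/panbind/benchmark.py` — LOO designs and ligand benchmark
- `src/panbind/distance.py` — pseudo-sequence allele distance
- `src/panbind/synthetic.py` — synthetic alleles, records, ligand fixtures
- `src/panbind/cli.py` — the `panbind` command
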