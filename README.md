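# refstab

Reference-gene stability evaluation for RT-qPCR cycle-threshold (Ct) data:

- **Amplification efficiency** from standard-curve dilution series
  (`E = (10^(-1/slope) - 1) x 100%`).
- **Four stability statistics**, all "lower = more stable" with dense ranks:
  comparative delta-Ct (mean pairwise SD of Ct differences), geNorm
  (M values, stepwise elimination, pairwise variation V_n/n+1 with the 0.15
  rule), NormFinder (variance decomposition after removing per-sample
  loading, with optional group structure and shrunken intergroup
  deviations), and BestKeeper (dispersion of raw Ct plus the per-sample
  geometric-mean index and correlations).
- **Consensus ranking**: geometric mean of the per-method ranks; the two
  smallest geometric means form the recommended reference pair.
- **Relative quantification**: multi-reference 2^-ddCt for a target gene
  with one-way ANOVA + Tukey HSD compact letter display across groups.
- **Synthetic data**: a seeded Ct generator (per-sample loading shifts,
  per-gene technical noise, per-group biological effects) with recorded
  ground-truth stability orderings, so the whole pipeline is testable
  without any external data.

## CLI

```sh
# standard curves: CSV with columns gene, log10_dilution, ct
refstab efficiency --input curve.csv

# simulate a study-like data set (long CSV + ground-truth JSON)
refstab simulate --condition tissues --seed 7 --out sim_ct.csv --truth truth.json

# stability methods + consensus; writes one TSV per method,
# genorm_v.tsv, consensus.tsv and report.json under --out
refstab stability --input sim_ct.csv --out report/

# target-gene 2^-ddCt against a reference set
refstab normalize --input sim_ct.csv --target UAP --refs RPL6,RPL13 \
    --calibrator foregut --out rq.tsv
```

Long input CSV columns: `sample, group, gene, replicate, ct`; a wide layout
(gene rows x sample columns) is also accepted with `--layout wide --groups
groups.csv`. Replicates are averaged per biological unit before analysis
(`--no-aggregate` keeps them as independent samples). Per-gene efficiencies
can be supplied with `--efficiency-table` (columns `gene,
efficiency_percent`); the default base is 2 (100%).

## Python API

```python
from refstab import (read_ct_table, to_relative_quantities, compute_stability,
                     build_rank_table, geomean_consensus)

t = read_ct_table("ct.csv", layout="long")
results = compute_stability(t)                # all four methods
cons = geomean_consensus(build_rank_table(list(results.values())))
print(cons.recommended_pair)
```

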