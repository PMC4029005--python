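# compbin

Composition-based binning and profiling for simple gut metagenomes.

Shotgun assembly of a microbial community yields contigs of unknown
origin.  For communities of moderate complexity — the motivating system is
the digestive tract of the medicinal leech *Hirudo verbana*, dominated by
a *Rikenella*-like bacterium and *Aeromonas veronii* with a handful of
less abundant genera — each genome carries a characteristic nucleotide
composition, so contigs can be grouped ("binned") by organism without any
reference database.  `compbin` implements this workflow end to end:

- **Features** (`compbin.features`): per-contig GC content and di- to
  penta-nucleotide frequencies, z-score normalized per column.
- **Binning** (`compbin.binning`, `compbin.pipeline`): two independent
  routes — PCA of the full composition matrix followed by best-of-100
  Euclidean K-means (k = 10), and an emergent self-organizing map (ESOM)
  trained on tetranucleotide frequencies whose U-matrix valleys define
  clusters.  Both clusterings are named by majority vote over a partial
  taxon-annotation table, and the consensus keeps a contig only when the
  two routes agree; conflicting contigs are `DISCARDED`.
- **Amplicon profiles** (`compbin.amplicon`): relative abundance,
  cumulative dominance of named taxa, and richness normalized by random
  subsampling without replacement (with the exact hypergeometric
  expectation `E[S] = Σ_t (1 − C(N−n_t, d)/C(N, d))` alongside).
- **Functional profiles** (`compbin.functional`): COG/KEGG-style category
  counts normalized by total hits, PCA across metagenomes,
  nearest-profile grouping, and two-profile comparison tables with a
  Spearman rank-concordance statistic.
- **Synthetic communities** (`compbin.synthetic`): order-k Markov-chain
  genomes with target GC and genome-specific transition skews,
  abundance-weighted contig sampling with a minimum length, shared ~1 kb
  repeat elements, partial labels, and multinomial amplicon/category
  count tables — everything the downstream stages assume, generated from
  one seed.

## Worked example

```python
from compbin import (
    RunConfig, bin_contigs, bin_summary, default_community_spec,
    simulate_community,
)

dataset = simulate_community(default_community_spec(), seed=1)
result = bin_contigs(dataset.contigs, dataset.labels, RunConfig(seed=1))
print(f"route agreement: {100 * result.agreement:.1f}%")
print(f"ESOM clusters:   {result.esom_cluster_count}")
print(bin_summary(result.bins, dataset.contigs)[["contig_count", "total_mb"]])
```

which prints

```
route agreement: 100.0%
ESOM clusters:   8
                contig_count  total_mb
taxon
Aeromonas                499      1.44
Bacteroides              179      0.50
Clostridium              208      0.59
Desulfovibrio             62      0.22
Erysipelothrix           140      0.40
Fusobacterium            103      0.26
Proteus                  233      0.64
Rikenella                576      1.72
```

The simulated community has eight genomes with GC spaced 0.05 apart and
distinct dinucleotide skews; both routes separate them cleanly, the ESOM
U-matrix shows eight valleys, and every contig's consensus bin matches
its true source genome (agreement 100%, nothing discarded).  The same
stages are exposed on the command line as
`compbin simulate | features | bin | amplicon | cogpca | stats`.

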