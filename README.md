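# psnscan

Phylogenetic classification from protein similarity networks.

Tree-based phylogenetic inference assumes strictly divergent evolution; a
complex-network view of the same data does not. `psnscan` implements that
view end-to-end: starting from a square matrix *S* of pairwise
percent-identity scores (e.g. all-vs-all BLAST over a protein family), it

1. **symmetrizes** the directional scores, *S<sub>ij</sub>* ←
   min(*S<sub>ij</sub>*, *S<sub>ji</sub>*);
2. builds the **threshold family** of unweighted networks — one graph per
   integer threshold σ ∈ [0, 100], with an edge (i, j) iff
   *S<sub>ij</sub>* ≥ σ;
3. summarizes each graph by its **neighborhood matrix** *M̂* =
   Σ<sub>ℓ</sub> ℓ·*M*(ℓ) (entry = shortest-path length; a sentinel *n* for
   unreachable pairs) and locates the **critical threshold** σ<sub>c</sub>
   as the peak of the inter-network distance
   δ(σ, σ+1) = Σ<sub>i&lt;j</sub> |*M̂*<sub>σ</sub> − *M̂*<sub>σ+1</sub>| / (n(n−1)/2);
4. characterizes the critical network with the standard index battery —
   ⟨k⟩, p(k), clustering *C* and *C*(k), ⟨d⟩, diameter *D*, node/edge
   betweenness, degree assortativity *Q*, box-covering fractal dimension
   *d<sub>b</sub>*, modularity *m<sub>d</sub>*;
5. detects **communities** with the Newman–Girvan procedure (repeatedly
   remove the largest-edge-betweenness edge, recording splits as a
   dendrogram) and selects the maximum-modularity cut;
6. attaches **branch support** by a binomial-resampling bootstrap: each
   *S<sub>ij</sub>*/100 becomes the success probability of a
   Binomial(*trials*, p) draw (*trials* = alignment length including gaps),
   *S′<sub>ij</sub>* = k·100/*trials*; the support of a branch is the
   percentage of replicate dendrograms containing that exact node set;
7. compares classifications with the **congruence index**
   *G*(φ, ψ) = 100·*Q*/*R* (*R* common organisms, *Q* co-assigned under the
   optimal one-to-one community matching).

The package ships the published classification of 42 basidiomycete chitin
synthase sequences (`psnscan.chs`: ids, accessions, species, CHS classes,
tree groups A/B/C, network communities C1/C2/C3) as reference data, plus a
planted-block synthetic generator (`psnscan.synth`) so the whole pipeline
is testable with known ground truth.

## Worked example

```sh
psnscan synth --blocks 12,12,12 --mu-in 80 --mu-out 30 --sd 5 --seed 7 \
        -o sim.tsv --truth truth.tsv
psnscan scan        -i sim.tsv -o out
psnscan communities -i sim.tsv -o out
psnscan bootstrap   -i sim.tsv -o out --replicates 200 --trials 4944 --seed 1
psnscan congruence  -a out/communities.tsv -b truth.tsv
```

prints (stderr log plus the congruence result):

```
wrote 36x36 matrix to sim.tsv
sigma_c = 40; wrote out/scan.json
sigma=40: 3 communities, modularity 0.6420; wrote out/communities.tsv
wrote out/support.tsv (71 branches)
{"R": 36, "Q": 36, "G": 100.0}
```

Reading: three planted families of 12 sequences (80 % identity within,
30 % between, noise sd 5) produce a δ profile peaking at σ<sub>c</sub> = 40
— the threshold where the similarity network disaggregates into its
evolutionarily meaningful groups.  Community detection at that threshold
recovers the three planted families exactly (congruence *G* = 100 against
the generator's truth), with maximum-modularity 0.642, and the bootstrap
gives the three family branches 100 % support (`out/support.tsv`).  All
outputs are plain TSV/JSON/Newick; `out/support.nwk` is the dendrogram
with support percentages as internal node labels.

The same analysis starting from raw BLAST tabular output:

```python
from psnscan import read_blast_tabular, from_pairwise_records, symmetrize, scan
S = symmetrize(from_pairwise_records(read_blast_tabular("allvsall.tsv")))
profile = scan(S)
print(profile.sigma_c, profile.secondary_peaks[:3])
```

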