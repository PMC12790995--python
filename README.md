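# paranome

Paralog-resolved pangenome analysis of high-identity gene families.

Recently expanded gene families sit inside segmental duplications whose
copies are >97% identical — close enough to allelic variation that
short-read mapping, and even naive assembly comparison, cannot tell
*which paralog* a sequence, a transcript, or a read belongs to. This
package implements the analysis chain needed to work with such a family
across a panel of haplotype-resolved assemblies:

* **Locus discovery and validation** — find every copy of an ~20 kbp
  duplicon in each haplotype (anchor-chaining mapper and/or external PAF
  alignments, merged by union), require intact unique flanks and no
  overlap with assembly-unreliability masks.
* **Phylogenetic paralog assignment** — name copies by supported
  monophyletic clades around reference anchors (SH-aLRT-style support
  threshold, merged "B12/B13"-style names where anchors are inseparable,
  novel "A1L1"-style names for well-separated anchor-free clades), and
  build copy-number tables with per-paralog heterozygosity
  (fraction of samples with discordant haplotype copy numbers).
* **Read-depth copy number** — fastCN-style 36 bp segment counting with
  ≤ 2 mismatches, calibrated against CN=2 regions, VNTR windows excluded.
* **Structural configurations** — encode each locus as a signed
  order of paralogs and marker genes; compare configurations with an
  exact DCJ-indel rearrangement distance (double-cut-and-join plus
  insertions/deletions of contiguous runs); midpoint-rooted NJ trees of
  configurations; inversion calls and inversion allele frequencies.
* **Interlocus gene conversion** — sliding nearest-consensus scan for
  tracts of donor-paralog sequence on acceptor copies, with
  donor × acceptor directionality matrices and hotspot rankings.
* **Selection statistics** — Tajima's D (exact 1989 constants) and nSL
  (identity-run lengths in SNP units, frequency-bin standardized) in
  sliding windows, with chromosome-wide percentile flags and an
  IGC-mask-excluded re-ranking.
* **Iso-seq gene models** — mismatch-delta read-to-paralog assignment
  (unique iff best beats second-best by ≥ 1 mismatch), longest-ORF
  calling with start-class detection (MFCC/MVKL/MRVR/MRLR), ≥ 5-molecule
  isoform models, and coding-VNTR profiling (SADD/MIISR frame-switch
  unit counts; 19- and 23-residue alternating units).
* **Unique k-mer expression** — 31-mer catalogs private to each
  paralog's gene models, iterative merging into detectable paralog
  groups (≥ 5 uniquely identifying positions), exclusive read
  classification, and per-tissue enrichment Z with permutation p-values.

Everything runs on synthetic gene families with planted truth
(`paranome.simulate`), including a forward Wright–Fisher simulator for
neutral and sweep haplotype panels — no downloads required.

## Worked example

Simulate a 4-paralog family on two diploid samples, plant one extra copy
of P3 on one haplotype and an inversion on another, then rediscover and
classify every copy:

```python
import numpy as np
from paranome.simulate import (simulate_family, plant_events,
                               simulate_transcripts, _mutate)
from paranome.loci import find_copies
from paranome.classify import distance_nj, assign_clades, copy_table
from paranome.isoforms import longest_orf, vntr_profile

fam = simulate_family(ancestor_len=16_000, n_paralogs=4, inter_div=0.03,
                      intra_div=0.001, n_samples=2, seed=7,
                      flank=5_000, spacer=5_000,
                      vntr_units={"P2": (7, 6, 5)})
fam = plant_events(fam, cn_changes=[("s1_h1", "P3", 1)],
                   inversions=[("s2_h2", 1, 2)], seed=1)

copies = {h: find_copies({h: fam.assembly(h)}, fam.ancestor_seq,
                         haplotype_id=h) for h in fam.haplotype_ids}
print({h: len(v) for h, v in copies.items()})
```

prints `{'s1_h1': 5, 's1_h2': 4, 's2_h1': 4, 's2_h2': 4}` — the planted
gain is found (5 copies on `s1_h1`, including the two reverse-strand
copies of the inversion on `s2_h2`). Building an NJ tree over the
extracted copies plus per-paralog anchor sequences and an outgroup, then
assigning clades and tabulating copy number:

```text
copy-number matrix:
haplotype  s1_h1  s1_h2  s2_h1  s2_h2
paralog
P1           1.0    1.0    1.0    1.0
P2           1.0    1.0    1.0    1.0
P3           2.0    1.0    1.0    1.0
P4           1.0    1.0    1.0    1.0
heterozygosity: {'P1': 0.0, 'P2': 0.0, 'P3': 0.5, 'P4': 0.0}
```

Every copy lands on its true paralog; P3's copy-number heterozygosity is
0.5 (one of two samples discordant), exactly the planted truth. The
transcript of the VNTR-carrying paralog round-trips through ORF calling:

```python
t = next(x for x in simulate_transcripts(fam)
         if x.paralog == "P2" and x.isoform == 1)
orf, start_class = longest_orf(t.cdna)
prof = vntr_profile(orf)
print(len(orf), start_class, (prof.n1, prof.n2, prof.n3))
```

prints `702 MVKL (7, 6, 5)` — a 702-residue protein with the MVKL
alternate start and the planted 7→6→5 SADD/MIISR/SADD repeat pattern.

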