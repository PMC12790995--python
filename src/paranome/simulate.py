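"""Synthetic gene-family pangenomes with planted truth.

The generator emulates the structure of a recently expanded, high-identity
segmental-duplication gene family: an ancestral ~20 kbp duplicon dispersed
as N paralogs whose inter-paralog divergence exceeds allelic diversity,
per-haplotype copy-number gain/loss, inversions repositioning copies,
interlocus gene-conversion (IGC) tracts copying sequence between paralogs,
a selective sweep in phased SNP haplotypes, and transcripts per paralog
carrying a variable in-frame coding VNTR.

Sequence evolution is substitution-only outside planted VNTRs so that
coordinate truth stays exact for breakpoint-recovery tests.  All
generators are pure functions of their seed.
"""

from __future__ import annotations

import copy as _copy
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .io import VariantMatrix
from .motifs import backtranslate, vntr_dna, vntr_protein

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)
_COMP = {"A": "T", "C": "G", "G": "C", "T": "A", "N": "N"}


def revcomp(seq: str) -> str:
    return "".join(_COMP[b] for b in reversed(seq))


def _rand_seq(rng: np.random.Generator, n: int) -> str:
    return rng.choice(_BASES, size=n).tobytes().decode()


def _mutate(rng: np.random.Generator, seq: str, rate: float) -> str:
    """Substitute bases independently at the given per-site rate."""
    if rate <= 0:
        return seq
    arr = np.frombuffer(seq.encode(), dtype=np.uint8).copy()
    hits = np.nonzero(rng.random(arr.size) < rate)[0]
    if hits.size:
        # shift each hit base by 1..3 in the ACGT alphabet: always a change
        idx = np.searchsorted(_BASES, arr[hits])
        arr[hits] = _BASES[(idx + rng.integers(1, 4, size=hits.size)) % 4]
    return arr.tobytes().decode()


# ---------------------------------------------------------------------------
# family truth
# ---------------------------------------------------------------------------


@dataclass
class CopySpec:
    """One gene-family copy on a haplotype (allele in its own forward frame)."""

    paralog: str
    allele_seq: str
    strand: str = "+"


@dataclass
class FamilyTruth:
    """Planted truth for a synthetic gene-family pangenome."""

    ancestor_seq: str
    paralog_seqs: dict[str, str]
    # per-haplotype alternating unique/copy elements: ("U", seq) | ("C", CopySpec)
    elements: dict[str, list]
    samples: dict[str, tuple[str, str]]  # sample -> (hap1_id, hap2_id)
    vntr_units: dict[str, tuple[int, int, int]] = field(default_factory=dict)
    vntr_pos: dict[str, tuple[int, int]] = field(default_factory=dict)  # paralog -> interval
    planted_igc: list = field(default_factory=list)  # (hap, copy_idx, donor, start, end)
    planted_inversions: list = field(default_factory=list)  # (hap, interval, symbols)
    inter_div: float = 0.0
    intra_div: float = 0.0
    rng_seed: int = 0

    # -- derived views -----------------------------------------------------

    @property
    def haplotype_ids(self) -> list[str]:
        return list(self.elements)

    def copies(self, hap: str) -> list[CopySpec]:
        return [el[1] for el in self.elements[hap] if el[0] == "C"]

    def planted_cn(self) -> pd.DataFrame:
        """sample x haplotype x paralog integer copy number (long form)."""
        rows = []
        for sample, haps in self.samples.items():
            for hap in haps:
                counts: dict[str, int] = {p: 0 for p in self.paralog_seqs}
                for c in self.copies(hap):
                    counts[c.paralog] += 1
                for p, n in counts.items():
                    rows.append({"sample": sample, "haplotype": hap, "paralog": p, "cn": n})
        return pd.DataFrame(rows)

    def assembly(self, hap: str) -> str:
        parts = []
        for kind, payload in self.elements[hap]:
            if kind == "U":
                parts.append(payload)
            else:
                parts.append(payload.allele_seq if payload.strand == "+" else revcomp(payload.allele_seq))
        return "".join(parts)

    def assemblies(self) -> dict[str, str]:
        return {hap: self.assembly(hap) for hap in self.elements}

    def placements(self, hap: str) -> list[tuple[str, int, int, str]]:
        """Planted copy coordinates: (paralog, start, end, strand) per copy."""
        out = []
        pos = 0
        for kind, payload in self.elements[hap]:
            if kind == "U":
                pos += len(payload)
            else:
                n = len(payload.allele_seq)
                out.append((payload.paralog, pos, pos + n, payload.strand))
                pos += n
        return out

    def configuration(self, hap: str) -> list[tuple[str, str]]:
        """Signed symbol list of the haplotype's copies, in coordinate order."""
        return [(p, s) for p, _, _, s in self.placements(hap)]


# ---------------------------------------------------------------------------
# family simulation
# ---------------------------------------------------------------------------


def simulate_family(
    ancestor_len: int = 20_000,
    n_paralogs: int = 8,
    inter_div: float = 0.03,
    intra_div: float = 0.001,
    seed: int = 0,
    n_samples: int = 1,
    flank: int = 30_000,
    spacer: int = 30_000,
    vntr_units: Mapping[str, tuple[int, int, int]] | None = None,
) -> FamilyTruth:
    """Simulate a dispersed gene family with one copy of each paralog per haplotype.

    ``inter_div`` and ``intra_div`` are target *pairwise* divergences:
    each paralog (allele) is mutated from its parent sequence at half the
    target rate, so two paralogs (alleles) differ at approximately the
    requested rate.  ``vntr_units`` optionally plants an in-frame tandem
    repeat (the exon-8 analog) into named paralogs at a fixed position;
    this is the only source of length variation between paralogs.
    """
    if n_paralogs < 1:
        raise ValueError("n_paralogs must be >= 1")
    if not (inter_div > intra_div >= 0):
        raise ValueError("require inter_div > intra_div >= 0")
    rng = np.random.default_rng(seed)
    ancestor = _rand_seq(rng, ancestor_len)
    names = [f"P{i + 1}" for i in range(n_paralogs)]
    paralog_seqs: dict[str, str] = {}
    vpos: dict[str, tuple[int, int]] = {}
    units = dict(vntr_units or {})
    insert_at = int(ancestor_len * 0.75)
    for name in names:
        seq = _mutate(rng, ancestor, inter_div / 2)
        if name in units:
            repeat = vntr_dna(*units[name])
            seq = seq[:insert_at] + repeat + seq[insert_at:]
            vpos[name] = (insert_at, insert_at + len(repeat))
        paralog_seqs[name] = seq

    # unique background is one genomic locus: shared across all haplotypes
    # (each haplotype carries an allele of it), so it is a true CN=2 region
    background = [_rand_seq(rng, flank)]
    for j in range(n_paralogs):
        background.append(_rand_seq(rng, spacer if j < n_paralogs - 1 else flank))

    elements: dict[str, list] = {}
    samples: dict[str, tuple[str, str]] = {}
    for si in range(n_samples):
        sample = f"s{si + 1}"
        hap_pair = []
        for hi in (1, 2):
            hap = f"{sample}_h{hi}"
            els: list = [("U", _mutate(rng, background[0], intra_div / 2))]
            for j, name in enumerate(names):
                allele = _mutate(rng, paralog_seqs[name], intra_div / 2)
                els.append(("C", CopySpec(name, allele, "+")))
                els.append(("U", _mutate(rng, background[j + 1], intra_div / 2)))
            elements[hap] = els
            hap_pair.append(hap)
        samples[sample] = tuple(hap_pair)
    return FamilyTruth(
        ancestor_seq=ancestor,
        paralog_seqs=paralog_seqs,
        elements=elements,
        samples=samples,
        vntr_units=units,
        vntr_pos=vpos,
        inter_div=inter_div,
        intra_div=intra_div,
        rng_seed=seed,
    )


def plant_events(
    family: FamilyTruth,
    cn_changes: Sequence[tuple[str, str, int]] = (),
    inversions: Sequence[tuple[str, int, int]] = (),
    igc_tracts: Sequence[tuple[str, int, str, int, int]] = (),
    seed: int = 0,
) -> FamilyTruth:
    """Plant copy-number changes, inversions, and IGC tracts; returns a new truth.

    * ``cn_changes``: (haplotype, paralog, delta) — delta > 0 inserts new
      alleles of the paralog after its last copy; delta < 0 removes copies.
    * ``inversions``: (haplotype, first_copy_idx, last_copy_idx) — the
      spanned segment (copies plus interior unique sequence) is
      reverse-complemented: strands flip and order reverses.
    * ``igc_tracts``: (haplotype, copy_idx, donor_paralog, start, length) —
      the acceptor interval is replaced with the donor paralog's
      homologous sequence (same coordinates, substitution-only model).

    Overlapping planted events on the same copy raise, keeping the truth
    unambiguous.
    """
    fam = _copy.deepcopy(family)
    rng = np.random.default_rng(seed)

    for hap, paralog, delta in cn_changes:
        if paralog not in fam.paralog_seqs:
            raise ValueError(f"unknown paralog {paralog!r}")
        els = fam.elements[hap]
        copy_positions = [i for i, (k, p) in enumerate(els) if k == "C" and p.paralog == paralog]
        if delta >= 0:
            anchor = copy_positions[-1] if copy_positions else len(els) - 2
            spacer_len = 30_000
            for kind, payload in els:
                if kind == "U":
                    spacer_len = len(payload)
                    break
            for _ in range(delta):
                allele = _mutate(rng, fam.paralog_seqs[paralog], fam.intra_div / 2)
                els.insert(anchor + 1, ("C", CopySpec(paralog, allele, "+")))
                els.insert(anchor + 1, ("U", _rand_seq(rng, spacer_len)))
        else:
            if len(copy_positions) < -delta:
                raise ValueError(f"cannot remove {-delta} copies of {paralog} from {hap}")
            for i in sorted(copy_positions[: -delta], reverse=True):
                del els[i]
                if i < len(els) and els[i][0] == "U" and i > 0 and els[i - 1][0] == "U":
                    els[i - 1] = ("U", els[i - 1][1] + els[i][1])
                    del els[i]

    igc_by_copy: dict[tuple[str, int], list[tuple[int, int]]] = {}
    for hap, copy_idx, donor, start, length in igc_tracts:
        copies = fam.copies(hap)
        if copy_idx >= len(copies):
            raise ValueError(f"no copy index {copy_idx} on {hap}")
        spec = copies[copy_idx]
        if donor == spec.paralog:
            raise ValueError("IGC donor must differ from the acceptor paralog")
        if donor not in fam.paralog_seqs:
            raise ValueError(f"unknown donor paralog {donor!r}")
        end = start + length
        if end > len(spec.allele_seq) or end > len(fam.paralog_seqs[donor]):
            raise ValueError("IGC tract outside acceptor/donor sequence")
        for s0, e0 in igc_by_copy.get((hap, copy_idx), []):
            if start < e0 and s0 < end:
                raise ValueError("overlapping planted IGC tracts")
        igc_by_copy.setdefault((hap, copy_idx), []).append((start, end))
        spec.allele_seq = (
            spec.allele_seq[:start] + fam.paralog_seqs[donor][start:end] + spec.allele_seq[end:]
        )
        fam.planted_igc.append((hap, copy_idx, donor, start, end))

    for hap, first, last in inversions:
        els = fam.elements[hap]
        copy_el_idx = [i for i, (k, _) in enumerate(els) if k == "C"]
        if not (0 <= first <= last < len(copy_el_idx)):
            raise ValueError("inversion copy indices out of range")
        lo, hi = copy_el_idx[first], copy_el_idx[last]
        placements = fam.placements(hap)  # pre-inversion coordinates/symbols
        sym = [placements[i][0] for i in range(first, last + 1)]
        interval = (placements[first][1], placements[last][2])
        segment = els[lo : hi + 1]
        flipped = []
        for kind, payload in reversed(segment):
            if kind == "U":
                flipped.append(("U", revcomp(payload)))
            else:
                flipped.append(
                    ("C", CopySpec(payload.paralog, payload.allele_seq, "-" if payload.strand == "+" else "+"))
                )
        els[lo : hi + 1] = flipped
        fam.planted_inversions.append((hap, interval, sym))

    return fam


# ---------------------------------------------------------------------------
# transcripts
# ---------------------------------------------------------------------------

_START_CLASSES = ("MFCC", "MVKL", "MRVR", "MRLR")

_AA_ORDER = "ACDEFGHIKLMNPQRSTVWY"


def _dna_to_protein_body(dna: str, n_aa: int) -> str:
    """Deterministically map paralog DNA onto an amino-acid body.

    Pairs of bases index the 20-letter alphabet, so paralog-specific
    substitutions propagate into protein (and hence cDNA) differences.
    """
    vals = {"A": 0, "C": 1, "G": 2, "T": 3}
    out = []
    for i in range(n_aa):
        a, b = dna[2 * i], dna[2 * i + 1]
        out.append(_AA_ORDER[(vals[a] * 4 + vals[b]) % 20])
    return "".join(out)


@dataclass
class TranscriptModel:
    paralog: str
    isoform: int
    cdna: str
    protein: str
    start_class: str
    n_exons: int
    vntr_units: tuple[int, int, int] | None


def simulate_transcripts(
    family: FamilyTruth,
    n_isoforms: int = 2,
    body_aa: int = 300,
    n_exons: int = 8,
) -> list[TranscriptModel]:
    """Per-paralog transcript models with paralog-specific coding bodies.

    Each paralog gets ``n_isoforms`` isoforms sharing a start class but
    differing in body length (an exon-skip analog).  If the family planted
    a genomic VNTR for the paralog, the same unit counts appear in frame
    in the transcript, so assembly-derived and cDNA-derived repeat counts
    can be compared.
    """
    out = []
    for pi, (name, seq) in enumerate(sorted(family.paralog_seqs.items())):
        start = _START_CLASSES[pi % len(_START_CLASSES)]
        units = family.vntr_units.get(name)
        utr5 = seq[100:220]
        utr3 = seq[300:450]
        body = _dna_to_protein_body(seq[1000:], body_aa)
        for iso in range(1, n_isoforms + 1):
            body_iso = body if iso == 1 else body[: 2 * body_aa // 3]
            protein = start + body_iso
            if units:
                protein += vntr_protein(*units)
            cdna = utr5 + backtranslate(protein) + "TAA" + utr3
            out.append(
                TranscriptModel(
                    paralog=name,
                    isoform=iso,
                    cdna=cdna,
                    protein=protein,
                    start_class=start,
                    n_exons=n_exons,
                    vntr_units=units,
                )
            )
    return out


# ---------------------------------------------------------------------------
# reads
# ---------------------------------------------------------------------------


def _apply_errors(rng: np.random.Generator, seq: str, err_rate: float) -> str:
    return _mutate(rng, seq, err_rate) if err_rate > 0 else seq


def simulate_reads(
    family: FamilyTruth,
    mode: str = "dna_short",
    depth: float = 30.0,
    read_len: int = 150,
    err_rate: float = 0.0,
    expression_profile: Mapping[str, float] | None = None,
    transcripts: Sequence[TranscriptModel] | None = None,
    sample: str | None = None,
    seed: int = 0,
) -> tuple[dict[str, str], pd.DataFrame]:
    """Simulate reads with a truth table mapping each read to its source.

    ``dna_short``: uniform genomic fragments from both haplotypes of one
    sample at the given *diploid* depth.  ``rna_short``: fragments of
    transcripts drawn by the expression profile.  ``isoseq``: full-length
    transcript molecules (``depth`` = molecule count), including any
    planted VNTR units.
    """
    if depth <= 0:
        raise ValueError("depth must be positive")
    rng = np.random.default_rng(seed)
    reads: dict[str, str] = {}
    rows = []
    if mode == "dna_short":
        sample = sample or next(iter(family.samples))
        haps = family.samples[sample]
        per_hap_depth = depth / len(haps)
        for hap in haps:
            genome = family.assembly(hap)
            n_reads = int(round(per_hap_depth * len(genome) / read_len))
            starts = rng.integers(0, len(genome) - read_len + 1, size=n_reads)
            flip = rng.random(n_reads) < 0.5
            for i, (st, fl) in enumerate(zip(starts, flip)):
                seq = genome[st : st + read_len]
                if fl:
                    seq = revcomp(seq)
                seq = _apply_errors(rng, seq, err_rate)
                name = f"{hap}_r{i}"
                reads[name] = seq
                rows.append({"read": name, "haplotype": hap, "start": int(st), "strand": "-" if fl else "+"})
    elif mode in ("rna_short", "isoseq"):
        if transcripts is None:
            transcripts = simulate_transcripts(family)
        profile = dict(expression_profile or {})
        known = {t.paralog for t in transcripts}
        for p in profile:
            if p not in known:
                raise ValueError(f"expression profile names unknown paralog {p!r}")
        if not profile:
            profile = {p: 1.0 for p in known}
        pool = [t for t in transcripts if profile.get(t.paralog, 0) > 0]
        weights = np.array([profile[t.paralog] for t in pool], dtype=float)
        if mode == "isoseq":
            n_reads = int(depth)
            weights /= weights.sum()
            picks = rng.choice(len(pool), size=n_reads, p=weights)
            for i, k in enumerate(picks):
                t = pool[k]
                name = f"iso_{t.paralog}_{t.isoform}_r{i}"
                reads[name] = _apply_errors(rng, t.cdna, err_rate)
                rows.append(
                    {
                        "read": name,
                        "paralog": t.paralog,
                        "isoform": t.isoform,
                        "n_exons": t.n_exons,
                        "vntr_units": "" if t.vntr_units is None else "-".join(map(str, t.vntr_units)),
                    }
                )
        else:
            weights = weights * np.array([len(t.cdna) for t in pool])
            weights /= weights.sum()
            total_bases = depth * sum(len(t.cdna) for t in pool)
            n_reads = int(total_bases / read_len)
            picks = rng.choice(len(pool), size=n_reads, p=weights)
            for i, k in enumerate(picks):
                t = pool[k]
                st = int(rng.integers(0, max(len(t.cdna) - read_len, 0) + 1))
                seq = t.cdna[st : st + read_len]
                if rng.random() < 0.5:
                    seq = revcomp(seq)
                name = f"rna_{t.paralog}_{t.isoform}_r{i}"
                reads[name] = _apply_errors(rng, seq, err_rate)
                rows.append({"read": name, "paralog": t.paralog, "isoform": t.isoform, "start": st})
    else:
        raise ValueError(f"unknown read mode {mode!r}")
    return reads, pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# forward Wright-Fisher sweep simulator
# ---------------------------------------------------------------------------


def simulate_sweep(
    n_haplotypes: int = 40,
    L: int = 500_000,
    mu: float = 1e-6,
    rho: float = 1e-6,
    s: float = 0.0,
    generations: int | None = None,
    N: int = 200,
    sample_at_freq: float = 0.80,
    seed: int = 0,
) -> tuple[VariantMatrix, dict]:
    """Forward Wright-Fisher simulation of N haplotypes with an optional sweep.

    Haploid population of N recombining haplotypes, infinite-sites
    mutation at ``mu``/bp/generation, uniform recombination ``rho``/bp.
    The defaults are human-like rates (~1e-8 per bp for both) rescaled by
    the same factor as the population size, keeping N*mu and N*rho at
    realistic values.
    With s > 0, a single favored allele is introduced at L/2 after
    burn-in and the run is restarted from the pre-sweep state until the
    allele escapes early loss; haplotypes are sampled when it first
    reaches ``sample_at_freq`` (an ongoing sweep — haplotype statistics
    need both allele pools present, so sampling mid-sweep is the
    standard design; fixation before sampling is recorded in the
    truth).  s = 0 gives the neutral null, sampled after burn-in.

    Returns the sampled biallelic SNPs (ancestral allele = REF = 0) plus
    a truth dict with the sweep site, its final frequency, and whether it
    fixed before sampling.
    """
    if s < 0:
        raise ValueError("s must be >= 0")
    if N < n_haplotypes:
        raise ValueError("population must be at least as large as the sample")
    rng = np.random.default_rng(seed)
    burnin = generations if generations is not None else 10 * N
    mu_region = mu * L
    r_region = rho * L

    pop = np.zeros((N, 0), dtype=np.uint8)
    positions = np.zeros(0, dtype=np.int64)
    pos_set: set[int] = set()
    sweep_col = -1  # column index of the favored allele, -1 if absent
    sweep_pos = L // 2

    def step(pop, positions, sweep_col, select: bool):
        Ncur = pop.shape[0]
        if select and sweep_col >= 0:
            w = np.where(pop[:, sweep_col] == 1, 1.0 + s, 1.0)
            p = w / w.sum()
            parents1 = rng.choice(Ncur, size=Ncur, p=p)
            parents2 = rng.choice(Ncur, size=Ncur, p=p)
        else:
            parents1 = rng.integers(0, Ncur, size=Ncur)
            parents2 = rng.integers(0, Ncur, size=Ncur)
        children = pop[parents1].copy()
        if r_region > 0 and positions.size:
            n_cross = rng.poisson(r_region, size=Ncur)
            # single crossover (the common case), vectorized over children
            one = np.nonzero(n_cross == 1)[0]
            if one.size:
                cuts = rng.integers(0, L, size=one.size)
                m = positions[None, :] >= cuts[:, None]
                children[one] = np.where(m, pop[parents2[one]], children[one])
            two = np.nonzero(n_cross == 2)[0]
            if two.size:
                c = np.sort(rng.integers(0, L, size=(two.size, 2)), axis=1)
                m = (positions[None, :] >= c[:, :1]) & (positions[None, :] < c[:, 1:])
                children[two] = np.where(m, pop[parents2[two]], children[two])
            for i in np.nonzero(n_cross > 2)[0]:
                cuts = np.sort(rng.integers(0, L, size=n_cross[i]))
                seg = np.searchsorted(cuts, positions, side="right") % 2
                mask = seg == 1
                children[i, mask] = pop[parents2[i], mask]
        # infinite-sites mutation
        n_mut = rng.poisson(Ncur * mu_region)
        if n_mut:
            new_pos = []
            carriers = []
            for _ in range(n_mut):
                ppos = int(rng.integers(0, L))
                if ppos in pos_set or ppos == sweep_pos:
                    continue
                pos_set.add(ppos)
                new_pos.append(ppos)
                carriers.append(int(rng.integers(0, Ncur)))
            if new_pos:
                block = np.zeros((Ncur, len(new_pos)), dtype=np.uint8)
                block[carriers, np.arange(len(new_pos))] = 1
                children = np.concatenate([children, block], axis=1)
                positions = np.concatenate([positions, np.array(new_pos, dtype=np.int64)])
        # prune fixed/lost columns (keep the sweep column regardless)
        counts = children.sum(axis=0)
        keep = (counts > 0) & (counts < Ncur)
        if sweep_col >= 0:
            keep[sweep_col] = True
        if not keep.all():
            for p in positions[~keep]:
                pos_set.discard(int(p))
            if sweep_col >= 0:
                sweep_col = int(keep[:sweep_col].sum())
            children = children[:, keep]
            positions = positions[keep]
        return children, positions, sweep_col

    for _ in range(burnin):
        pop, positions, _ = step(pop, positions, -1, False)

    truth = {"sweep_pos": sweep_pos, "s": s, "fixed": False, "final_freq": 0.0, "attempts": 0}
    if s > 0:
        base_pop, base_positions = pop.copy(), positions.copy()
        base_pos_set = set(pos_set)
        max_gens = 200 * N
        while True:
            truth["attempts"] += 1
            pop, positions = base_pop.copy(), base_positions.copy()
            pos_set.clear()
            pos_set.update(base_pos_set)
            col = np.zeros((N, 1), dtype=np.uint8)
            col[int(rng.integers(0, N)), 0] = 1
            pop = np.concatenate([pop, col], axis=1)
            positions = np.concatenate([positions, np.array([sweep_pos], dtype=np.int64)])
            sweep_col = pop.shape[1] - 1
            ok = False
            for _ in range(max_gens):
                pop, positions, sweep_col = step(pop, positions, sweep_col, True)
                freq = pop[:, sweep_col].mean()
                if freq == 0:
                    break
                if freq >= sample_at_freq:
                    ok = True
                    break
            if ok:
                truth["fixed"] = bool(pop[:, sweep_col].all())
                truth["final_freq"] = float(pop[:, sweep_col].mean())
                break

    sample_idx = rng.choice(N, size=n_haplotypes, replace=False)
    sampled = pop[sample_idx]
    counts = sampled.sum(axis=0)
    seg = (counts > 0) & (counts < n_haplotypes)
    sampled = sampled[:, seg]
    positions = positions[seg]
    order = np.argsort(positions)
    sampled = sampled[:, order]
    positions = positions[order]
    hap_ids = [f"hap{i + 1}" for i in range(n_haplotypes)]
    sample_to_haps = {f"s{i + 1}": [2 * i, 2 * i + 1] for i in range(n_haplotypes // 2)}
    vm = VariantMatrix(
        contig="sim",
        positions=positions,
        alleles=[("A", "T")] * positions.size,
        haplotypes=sampled,
        haplotype_ids=hap_ids,
        sample_to_haplotypes=sample_to_haps,
    )
    return vm, truth
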