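"""Synthetic genomes with planted rearrangements, read simulation, and the
benchmark metrics used to assess a structural-variant caller.

``plant_svs`` edits a reference into one or two haplotypes carrying simple
events (deletion, inversion, tandem/dispersed duplication, translocation)
and the recurrent complex classes (inverted duplication, deletion-inversion,
deletion-duplication, deletion-inversion-duplication), optionally decorating
novel junctions with micro-insertions and short tandem repeats as seen at
real breakpoints.  ``simulate_reads`` draws paired-end reads (101 bp,
insert 500 +- 50 by default) from the haplotypes; ``reads_to_bam`` places
them into a coordinate-sorted BAM using the known haplotype-to-reference
segment map, soft-clipping reads across novel junctions and flipping strand
inside inverted segments.  Evaluation follows reciprocal-overlap matching
for simple events and junction-level comparison for complex ones.
"""

from __future__ import annotations

import dataclasses
import os
from dataclasses import dataclass, field

import numpy as np
import pysam
from pyfaidx import Fasta
from scipy.stats import rankdata

COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")

SIMPLE_TYPES = ("DEL", "INV", "DUP_TANDEM", "DUP_DISPERSED", "TRA")
CSV_TYPES = ("INV_DUP", "DEL_INV", "DEL_DUP", "DEL_INV_DUP")


def revcomp(seq: str) -> str:
    return seq.translate(COMPLEMENT)[::-1]


# ---------------------------------------------------------------------------
# Haplotype construction
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class Segment:
    """A piece of a haplotype: a reference slice (possibly inverted) or an
    inserted novel sequence (``start is None``)."""

    start: int | None
    end: int | None
    strand: str = "+"
    seq: str | None = None

    def length(self) -> int:
        return len(self.seq) if self.seq is not None else self.end - self.start


@dataclass
class TruthRecord:
    """One planted event: its type, zygosity, affected reference region,
    replacement layout (as (start, end, strand) reference slices) and the
    novel junctions it creates, keyed (exit_coord, exit_dir, entry_coord,
    entry_dir)."""

    type: str
    zygosity: str           # "hom" | "het"
    chrom: str
    region: tuple[int, int]
    intervals: dict = field(default_factory=dict)
    layout: list = field(default_factory=list)
    junctions: list = field(default_factory=list)
    decorations: list = field(default_factory=list)   # (junction index, seq)


@dataclass
class PlantedSV:
    """Specification of one event to plant.

    ``intervals`` meaning by type:
      DEL/INV/DUP_TANDEM: {"span": (s, e)} (+ "copies" for DUP_TANDEM)
      DUP_DISPERSED/TRA/INV_DUP: {"span": (s, e), "insert_at": p}
      DEL_INV/DEL_DUP: {"a": (s1, s2), "b": (s2, s3)}
      DEL_INV_DUP: {"a": (s1, s2), "b": (s2, s3), "c": (s3, s4)}
    """

    type: str
    chrom: str
    intervals: dict
    zygosity: str = "hom"
    copies: int = 2


def _event_region(ev: PlantedSV) -> tuple[int, int]:
    coords = []
    for v in ev.intervals.values():
        if isinstance(v, tuple):
            coords.extend(v)
        else:
            coords.append(v)
    return min(coords), max(coords)


def _event_layout(ev: PlantedSV) -> list[tuple[int, int, str]]:
    """Replacement layout for the event's region, as reference slices."""
    iv = ev.intervals
    t = ev.type
    if t == "DEL":
        return []
    if t == "INV":
        s, e = iv["span"]
        return [(s, e, "-")]
    if t == "DUP_TANDEM":
        s, e = iv["span"]
        return [(s, e, "+")] * ev.copies
    if t in ("DUP_DISPERSED", "TRA", "INV_DUP"):
        s, e = iv["span"]
        p = iv["insert_at"]
        strand = "-" if t == "INV_DUP" else "+"
        keep_src = t != "TRA"
        region = _event_region(ev)
        out = []
        cur = region[0]
        for x in sorted({s, e, p, region[1]}):
            if cur < x:
                if (cur, x) == (s, e):
                    if keep_src:
                        out.append((s, e, "+"))
                else:
                    out.append((cur, x, "+"))
            if x == p:
                out.append((s, e, strand))
            cur = x
        return out
    if t == "DEL_INV":
        return [(iv["b"][0], iv["b"][1], "-")]
    if t == "DEL_DUP":
        b = iv["b"]
        return [(b[0], b[1], "+"), (b[0], b[1], "+")]
    if t == "DEL_INV_DUP":
        b, c = iv["b"], iv["c"]
        return [(b[0], b[1], "-"), (c[0], c[1], "+"), (c[0], c[1], "+")]
    raise ValueError(f"unknown SV type {t!r}")


def layout_junctions(layout, region_start: int, region_end: int):
    """Novel junctions of a replacement layout, including its flank joins.

    Each junction is (exit_coord, exit_dir, entry_coord, entry_dir): the
    reference coordinate and direction at which sequence leaves one segment
    and enters the next.  Reference-collinear joins are omitted.
    """
    elems = ([(None, region_start, "+")] + list(layout)
             + [(region_end, None, "+")])
    out = []
    for (s1, e1, o1), (s2, e2, o2) in zip(elems, elems[1:]):
        exit_c = e1 if o1 == "+" else s1
        entry_c = s2 if o2 == "+" else e2
        if o1 == "+" and o2 == "+" and exit_c == entry_c:
            continue
        out.append((exit_c, o1, entry_c, o2))
    return out


def _novel_gaps(layout, region_start: int, region_end: int):
    """Indices of the inter-element gaps (0..len(layout)) that are novel
    junctions, in the same order layout_junctions reports them."""
    elems = ([(None, region_start, "+")] + list(layout)
             + [(region_end, None, "+")])
    out = []
    for g, ((s1, e1, o1), (s2, e2, o2)) in enumerate(zip(elems, elems[1:])):
        exit_c = e1 if o1 == "+" else s1
        entry_c = s2 if o2 == "+" else e2
        if o1 == "+" and o2 == "+" and exit_c == entry_c:
            continue
        out.append(g)
    return out


def _check_non_overlapping(events):
    regions = {}
    for ev in events:
        regions.setdefault(ev.chrom, []).append(_event_region(ev))
    for chrom, regs in regions.items():
        regs.sort()
        for (s1, e1), (s2, e2) in zip(regs, regs[1:]):
            if s2 < e1:
                raise ValueError(f"overlapping planted events on {chrom}: "
                                 f"({s1},{e1}) and ({s2},{e2})")


def _decoration(rng: np.random.Generator) -> str:
    """Micro-insertion (0-10 bp) or short tandem repeat (2-6 bp x 2-5)."""
    if rng.random() < 0.5:
        n = int(rng.integers(0, 11))
        return "".join(rng.choice(list("ACGT"), n))
    unit = "".join(rng.choice(list("ACGT"), int(rng.integers(2, 7))))
    return unit * int(rng.integers(2, 6))


def plant_svs(reference: str, events: list[PlantedSV], seed: int = 0,
              decorate_prob: float = 0.3):
    """Build two haplotypes carrying the given events.

    Heterozygous events are applied to haplotype 0 only; homozygous events to
    both.  With probability *decorate_prob*, each novel junction receives a
    junction decoration (micro-insertion or STR).  Returns
    ``(haplotypes, truth)`` where haplotypes is a list of two
    ``{chrom: [Segment, ...]}`` maps and truth a list of TruthRecords.
    """
    _check_non_overlapping(events)
    fa = Fasta(reference, as_raw=True)
    rng = np.random.default_rng(seed)
    truth = []
    decor_by_event = {}
    for i, ev in enumerate(events):
        region = _event_region(ev)
        layout = _event_layout(ev)
        junctions = layout_junctions(layout, region[0], region[1])
        decorations = []
        for j in range(len(junctions)):
            if rng.random() < decorate_prob:
                decorations.append((j, _decoration(rng)))
        decor_by_event[i] = dict(decorations)
        truth.append(TruthRecord(ev.type, ev.zygosity, ev.chrom, region,
                                 dict(ev.intervals), layout, junctions,
                                 decorations))
    haplotypes = []
    for hap_idx in (0, 1):
        hap = {}
        for chrom in fa.keys():
            clen = len(fa[chrom])
            evs = sorted(((i, ev) for i, ev in enumerate(events)
                          if ev.chrom == chrom
                          and (ev.zygosity == "hom" or hap_idx == 0)),
                         key=lambda t: _event_region(t[1])[0])
            segs = []
            cur = 0
            for i, ev in evs:
                rs, re_ = _event_region(ev)
                if cur < rs:
                    segs.append(Segment(cur, rs))
                layout = truth[i].layout
                gaps = _novel_gaps(layout, rs, re_)
                # decoration j (by junction order) sits in gap gaps[j]
                deco_at_gap = {gaps[j]: seq
                               for j, seq in decor_by_event[i].items() if seq}
                for g in range(len(layout) + 1):
                    if g in deco_at_gap:
                        segs.append(Segment(None, None, "+", deco_at_gap[g]))
                    if g < len(layout):
                        s, e, o = layout[g]
                        segs.append(Segment(s, e, o))
                cur = re_
            if cur < clen:
                segs.append(Segment(cur, clen))
            hap[chrom] = segs
        haplotypes.append(hap)
    return haplotypes, truth


def haplotype_sequence(segments: list[Segment], fasta: Fasta, chrom: str) -> str:
    parts = []
    for seg in segments:
        if seg.seq is not None:
            parts.append(seg.seq)
        else:
            s = str(fasta[chrom][seg.start:seg.end])
            parts.append(s if seg.strand == "+" else revcomp(s))
    return "".join(parts)


def write_haplotype_fastas(haplotypes, reference: str, out_prefix: str):
    """Write each haplotype to ``<prefix>.hap<k>.fa``; returns the paths."""
    fa = Fasta(reference, as_raw=True)
    paths = []
    for k, hap in enumerate(haplotypes):
        path = f"{out_prefix}.hap{k}.fa"
        with open(path, "w") as fh:
            for chrom, segs in hap.items():
                seq = haplotype_sequence(segs, fa, chrom)
                fh.write(f">{chrom}\n")
                for i in range(0, len(seq), 70):
                    fh.write(seq[i:i + 70] + "\n")
        paths.append(path)
    return paths


# ---------------------------------------------------------------------------
# Read simulation
# ---------------------------------------------------------------------------

@dataclass
class SimulatedPair:
    """A read pair in haplotype coordinates: fragment [start, start+isize) on
    (hap_idx, chrom); read 1 is the leftmost 5' read."""

    hap_idx: int
    chrom: str
    start: int
    isize: int
    seq1: str
    seq2: str


def simulate_reads(haplotypes, reference: str, depth: float,
                   read_len: int = 101, mu_is: float = 500.0,
                   sigma_is: float = 50.0, error_rate: float = 0.0,
                   seed: int = 0) -> list[SimulatedPair]:
    """Uniform paired-end simulation at total depth *depth* split evenly
    across haplotypes.  Insert lengths ~ N(mu_is, sigma_is^2) (clamped to
    at least 2*read_len); forward-reverse orientation on the generating
    haplotype; substitution errors at *error_rate* per base."""
    fa = Fasta(reference, as_raw=True)
    rng = np.random.default_rng(seed)
    bases = np.array(list("ACGT"))
    pairs = []
    for hap_idx, hap in enumerate(haplotypes):
        for chrom, segs in hap.items():
            seq = haplotype_sequence(segs, fa, chrom).upper()
            L = len(seq)
            n_pairs = int(round(depth / len(haplotypes) * L / (2 * read_len)))
            isizes = np.maximum(
                np.rint(rng.normal(mu_is, sigma_is, n_pairs)).astype(int),
                2 * read_len)
            starts = rng.integers(0, np.maximum(1, L - isizes))
            for s, isz in zip(starts.tolist(), isizes.tolist()):
                r1 = seq[s:s + read_len]
                r2 = revcomp(seq[s + isz - read_len:s + isz])
                if error_rate > 0:
                    r1 = _mutate(r1, error_rate, rng, bases)
                    r2 = _mutate(r2, error_rate, rng, bases)
                pairs.append(SimulatedPair(hap_idx, chrom, s, isz, r1, r2))
    return pairs


def _mutate(seq: str, rate: float, rng, bases) -> str:
    arr = np.array(list(seq))
    hit = rng.random(len(arr)) < rate
    if hit.any():
        arr[hit] = bases[rng.integers(0, 4, int(hit.sum()))]
    return "".join(arr)


def write_fastq(pairs: list[SimulatedPair], out_prefix: str):
    """Write reads to ``<prefix>_1.fq`` / ``<prefix>_2.fq``."""
    p1, p2 = f"{out_prefix}_1.fq", f"{out_prefix}_2.fq"
    with open(p1, "w") as f1, open(p2, "w") as f2:
        for i, pr in enumerate(pairs):
            q1 = "I" * len(pr.seq1)
            q2 = "I" * len(pr.seq2)
            f1.write(f"@sim{i}/1\n{pr.seq1}\n+\n{q1}\n")
            f2.write(f"@sim{i}/2\n{pr.seq2}\n+\n{q2}\n")
    return p1, p2


# ---------------------------------------------------------------------------
# Projection alignment (haplotype -> reference BAM)
# ---------------------------------------------------------------------------

MIN_ANCHOR = 20  # bp of a read that must sit in one reference segment


def _segment_table(segments: list[Segment]):
    """Prefix offsets for the haplotype's segments."""
    offs = []
    pos = 0
    for seg in segments:
        offs.append((pos, pos + seg.length(), seg))
        pos += seg.length()
    return offs


def _project_read(offs, s: int, e: int):
    """Best reference placement of haplotype interval [s, e).

    Returns (ref_start, aligned_len, strand, clip_left, clip_right) or None;
    clip sides are in haplotype-forward orientation.
    """
    best = None
    for hs, he, seg in offs:
        if seg.start is None or he <= s or hs >= e:
            continue
        os_, oe = max(s, hs), min(e, he)
        if best is None or oe - os_ > best[0]:
            best = (oe - os_, hs, he, seg, os_, oe)
    if best is None or best[0] < MIN_ANCHOR:
        return None
    _, hs, he, seg, os_, oe = best
    if seg.strand == "+":
        ref_start = seg.start + (os_ - hs)
    else:
        ref_start = seg.end - (oe - hs)
    return ref_start, oe - os_, seg.strand, os_ - s, e - oe


def reads_to_bam(pairs: list[SimulatedPair], haplotypes, reference: str,
                 out_bam: str, read_len: int = 101) -> str:
    """Place simulated pairs into a coordinate-sorted, indexed BAM.

    Each read is anchored on the reference segment holding the longest part
    of it; bases beyond that segment (novel junction overhangs, inserted
    sequence) are soft-clipped; reads from inverted segments flip strand.
    Reads without a >=20 bp anchor are dropped (their mate is written with
    the mate-unmapped flag).  Records are staged as SAM text for speed,
    then sorted and indexed.
    """
    fa = Fasta(reference, as_raw=True)
    tables = [{chrom: _segment_table(segs) for chrom, segs in hap.items()}
              for hap in haplotypes]
    qual = "I" * read_len
    tmp = out_bam + ".unsorted.sam"
    with open(tmp, "w") as out:
        out.write("@HD\tVN:1.6\tSO:unsorted\n")
        for c in fa.keys():
            out.write(f"@SQ\tSN:{c}\tLN:{len(fa[c])}\n")
        for i, pr in enumerate(pairs):
            offs = tables[pr.hap_idx][pr.chrom]
            s1, e1 = pr.start, pr.start + read_len
            s2, e2 = pr.start + pr.isize - read_len, pr.start + pr.isize
            projs = (_project_read(offs, s1, e1), _project_read(offs, s2, e2))
            seqs = (pr.seq1, revcomp(pr.seq2))
            recs = []
            for which, (proj, seq_fwd) in enumerate(zip(projs, seqs)):
                if proj is None:
                    recs.append(None)
                    continue
                ref_start, alen, strand, cl, cr = proj
                if strand == "+":
                    seq = seq_fwd
                    cig = (f"{cl}S" if cl else "") + f"{alen}M" + (f"{cr}S" if cr else "")
                else:
                    seq = revcomp(seq_fwd)
                    cig = (f"{cr}S" if cr else "") + f"{alen}M" + (f"{cl}S" if cl else "")
                # read 1 is haplotype-forward, read 2 haplotype-reverse
                reverse = (strand == "+") != (which == 0)
                recs.append([ref_start, alen, reverse, seq, cig, which])
            for a, b in ((recs[0], recs[1]), (recs[1], recs[0])):
                if a is None:
                    continue
                ref_start, alen, reverse, seq, cig, which = a
                flag = 1 | (64 if which == 0 else 128) | (16 if reverse else 0)
                if b is None:
                    flag |= 8
                    pnext, tlen = ref_start + 1, 0
                else:
                    if b[2]:
                        flag |= 32
                    pnext = b[0] + 1
                    lo = min(ref_start, b[0])
                    hi = max(ref_start + alen, b[0] + b[1])
                    tlen = (hi - lo) if ref_start <= b[0] else -(hi - lo)
                    if (not reverse) == (ref_start <= b[0]) and reverse != b[2]:
                        flag |= 2
                out.write(f"sim{i}\t{flag}\t{pr.chrom}\t{ref_start + 1}\t60\t"
                          f"{cig}\t=\t{pnext}\t{tlen}\t{seq}\t{qual}\n")
    pysam.sort("-o", out_bam, tmp)
    os.unlink(tmp)
    pysam.index(out_bam)
    return out_bam


def simulate_to_bam(haplotypes, reference: str, depth: float, out_bam: str,
                    read_len: int = 101, mu_is: float = 500.0,
                    sigma_is: float = 50.0, error_rate: float = 0.0,
                    seed: int = 0) -> str:
    pairs = simulate_reads(haplotypes, reference, depth, read_len, mu_is,
                           sigma_is, error_rate, seed)
    return reads_to_bam(pairs, haplotypes, reference, out_bam, read_len)


# ---------------------------------------------------------------------------
# Evaluation
# ---------------------------------------------------------------------------

def reciprocal_overlap(a: tuple[int, int], b: tuple[int, int]) -> float:
    """min(|a&b|/|a|, |a&b|/|b|); 0 for disjoint or empty intervals."""
    inter = min(a[1], b[1]) - max(a[0], b[0])
    if inter <= 0 or a[1] <= a[0] or b[1] <= b[0]:
        return 0.0
    return min(inter / (a[1] - a[0]), inter / (b[1] - b[0]))


def _truth_interval(rec: TruthRecord) -> tuple[int, int]:
    if "span" in rec.intervals:
        return tuple(rec.intervals["span"])
    return rec.region


def evaluate_simple(calls, truth, ro_threshold: float = 0.5,
                    merge_dup_fp: bool = True):
    """Per-type sensitivity and FDR by strict >50 % reciprocal overlap.

    *calls*: iterables with .type/.chrom/.start/.end attributes (SVCall) or
    (type, chrom, start, end) tuples.  Duplications are special-cased: each
    duplication flavour is scored separately for sensitivity, but for the FP
    count a called duplication matching *any* simulated duplication is not
    false.
    """
    def norm(c):
        if hasattr(c, "type"):
            return c.type, c.chrom, c.start, c.end
        return c

    calls = [norm(c) for c in calls]
    truth = [t for t in truth if t.type in SIMPLE_TYPES]
    results = {}
    dup_types = {"DUP_TANDEM", "DUP_DISPERSED"}
    for svtype in sorted({t.type for t in truth}):
        t_of_type = [t for t in truth if t.type == svtype]
        c_of_type = [c for c in calls if c[0] == svtype]
        matched = set()
        tp = 0
        for t in t_of_type:
            ti = _truth_interval(t)
            for idx, c in enumerate(c_of_type):
                if idx in matched or c[1] != t.chrom:
                    continue
                if reciprocal_overlap((c[2], c[3]), ti) > ro_threshold:
                    matched.add(idx)
                    tp += 1
                    break
        fp = 0
        for idx, c in enumerate(c_of_type):
            if idx in matched:
                continue
            ok_truth = [t for t in truth
                        if (t.type in dup_types if (merge_dup_fp and svtype in dup_types)
                            else t.type == svtype)]
            if any(c[1] == t.chrom and
                   reciprocal_overlap((c[2], c[3]), _truth_interval(t)) > ro_threshold
                   for t in ok_truth):
                continue
            fp += 1
        n_called = len(c_of_type)
        results[svtype] = {
            "sensitivity": tp / len(t_of_type) if t_of_type else float("nan"),
            "fdr": fp / n_called if n_called else 0.0,
            "tp": tp, "fp": fp,
            "n_truth": len(t_of_type), "n_called": n_called,
        }
    return results


def match_junction(pred, true, tol: int = 50) -> bool:
    """Same exit/entry directions, both coordinates within *tol* bp."""
    return (pred[1] == true[1] and pred[3] == true[3]
            and abs(pred[0] - true[0]) <= tol and abs(pred[2] - true[2]) <= tol)


def evaluate_csv(predicted_junctions_by_region, truth, tol: int = 50):
    """Junction-level comparison for complex events.

    *predicted_junctions_by_region*: mapping truth index -> list of predicted
    novel junctions in that event's region.  Matched junctions are TPs;
    unmatched predicted junctions in the region are FPs; unmatched truth
    junctions count against sensitivity.  Returns per-event dicts and the
    overall junction sensitivity.
    """
    per_event = []
    total_tp = total_truth = total_fp = 0
    for i, rec in enumerate(truth):
        preds = list(predicted_junctions_by_region.get(i, []))
        used = set()
        tp = 0
        for tj in rec.junctions:
            for k, pj in enumerate(preds):
                if k in used:
                    continue
                if match_junction(pj, tj, tol):
                    used.add(k)
                    tp += 1
                    break
        fp = len(preds) - len(used)
        per_event.append({"tp": tp, "fp": fp, "n_truth": len(rec.junctions)})
        total_tp += tp
        total_fp += fp
        total_truth += len(rec.junctions)
    return {
        "per_event": per_event,
        "junction_sensitivity": total_tp / total_truth if total_truth else float("nan"),
        "total_fp": total_fp,
    }


def rank_normalize(scores) -> np.ndarray:
    """Map scores to [0, 1] by rank: lowest -> 0, highest -> 1."""
    x = np.asarray(scores, float)
    if len(x) == 1:
        return np.array([1.0])
    return (rankdata(x) - 1.0) / (len(x) - 1.0)


# ---------------------------------------------------------------------------
# Reference construction helper
# ---------------------------------------------------------------------------

def random_reference(path: str, chrom_lengths: dict[str, int], seed: int = 0,
                     line: int = 70) -> str:
    """Write a random A/C/G/T reference FASTA (uniform base composition)."""
    rng = np.random.default_rng(seed)
    with open(path, "w") as fh:
        for chrom, L in chrom_lengths.items():
            seq = "".join(np.char.asarray(list("ACGT"))[rng.integers(0, 4, L)])
            fh.write(f">{chrom}\n")
            for i in range(0, L, line):
                fh.write(seq[i:i + line] + "\n")
    return path
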