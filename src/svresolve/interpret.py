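"""Interpretation of converged structures as structural-variant calls.

A converged allele is a sequence of oriented blocks over the cluster's
block alphabet.  The edit relative to the reference ordering names the
event: an absent block is a deletion; an extra adjacent copy a tandem
duplication; an extra copy elsewhere a dispersed duplication with its
insertion point; an in-place orientation flip an inversion; a block moved
without copy gain an intra-chromosomal translocation.  Clusters combining
several edit kinds become complex calls (CSV) labelled by the sorted set of
kinds (DEL+INV, INV+DUP, ...).  A call is homozygous when both alleles
carry the identical edit.  Calls serialize to VCFv4.1 (symbolic ALT records
for deletions, duplications and inversions; breakend pairs for dispersed
duplications, translocations and complex calls) and to a one-line-per-
cluster custom format carrying both allele structure strings.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from pyfaidx import Fasta

from .rearrange import (Structure, structure_from_string, structure_to_string,
                        reference_structure)

CSV_SUBTYPES = {
    frozenset({"DEL", "INV"}): "DEL+INV",
    frozenset({"DEL", "DUP"}): "DEL+DUP",
    frozenset({"DUP", "INV"}): "INV+DUP",
    frozenset({"DEL", "DUP", "INV"}): "DEL+DUP+INV",
}


@dataclass
class Edit:
    kind: str                   # DEL | DUP_TANDEM | DUP_DISPERSED | INV | TRA
    start: int                  # source interval, reference coordinates
    end: int
    insert_point: int | None = None
    inverted: bool = False

    def key(self):
        return (self.kind, self.start, self.end, self.insert_point, self.inverted)


@dataclass
class SVCall:
    type: str                   # DEL | DUP_TANDEM | DUP_DISPERSED | INV | TRA | CSV
    chrom: str
    start: int
    end: int
    genotype: str               # "hom" | "het"
    csv_subtype: str = ""
    insert_point: int | None = None
    allele_a: str = ""
    allele_b: str = ""
    score: float = 0.0
    bps: list = field(default_factory=list)
    edits: list = field(default_factory=list)


# ---------------------------------------------------------------------------
# Structure -> edits
# ---------------------------------------------------------------------------

def _tokenize(structure: Structure):
    """Collapse a structure into maximal collinear runs.

    A token (lo, hi, orient, pos) covers blocks lo..hi: an ascending all-'+'
    run, or a descending all-'-' run (a locally inverted range).
    """
    tokens = []
    i = 0
    while i < len(structure):
        b, o = structure[i]
        j = i + 1
        if o > 0:
            while (j < len(structure) and structure[j][1] > 0
                   and structure[j][0] == structure[j - 1][0] + 1):
                j += 1
            tokens.append((b, structure[j - 1][0], +1, i))
        else:
            while (j < len(structure) and structure[j][1] < 0
                   and structure[j][0] == structure[j - 1][0] - 1):
                j += 1
            tokens.append((structure[j - 1][0], b, -1, i))
        i = j
    return tokens


def _kept_tokens(tokens):
    """Tokens retained "in place": the disjoint, reference-ordered token
    subset covering the most blocks (weighted longest increasing
    subsequence over block ranges)."""
    n = len(tokens)
    best = [0] * n
    prev = [-1] * n
    for i, (lo, hi, _, _) in enumerate(tokens):
        w = hi - lo + 1
        best[i] = w
        for j in range(i):
            jlo, jhi, _, _ = tokens[j]
            if jhi < lo and best[j] + w > best[i]:
                best[i] = best[j] + w
                prev[i] = j
    kept = set()
    if n:
        i = max(range(n), key=lambda k: best[k])
        while i >= 0:
            kept.add(i)
            i = prev[i]
    return kept


def allele_edits(structure: Structure, bps: list[int]) -> list[Edit]:
    """Minimal-edit interpretation of one allele against the reference.

    Kept (in-place) tokens are found by a weighted ordered-subset match to
    the reference; uncovered blocks are deletions, kept inverted tokens are
    inversions, and unkept tokens become duplication copies (tandem when a
    neighbouring symbol repeats the same block) or moved blocks depending on
    whether their blocks also occur elsewhere.
    """
    n_blocks = len(bps) - 1
    cover = {b: 0 for b in range(1, n_blocks + 1)}
    for b, _ in structure:
        cover[b] += 1
    edits: list[Edit] = []

    # deletions: maximal runs of uncovered blocks
    b = 1
    while b <= n_blocks:
        if cover[b] == 0:
            b2 = b
            while b2 + 1 <= n_blocks and cover[b2 + 1] == 0:
                b2 += 1
            edits.append(Edit("DEL", bps[b - 1], bps[b2]))
            b = b2 + 1
        else:
            b += 1

    tokens = _tokenize(structure)
    kept = _kept_tokens(tokens)

    for ti, (lo, hi, orient, pos) in enumerate(tokens):
        if ti in kept:
            if orient < 0:
                edits.append(Edit("INV", bps[lo - 1], bps[hi], inverted=True))
            continue
        # unkept token: split into maximal runs of equal coverage class
        b = lo
        while b <= hi:
            dup = cover[b] >= 2
            b2 = b
            while b2 + 1 <= hi and (cover[b2 + 1] >= 2) == dup:
                b2 += 1
            interval = (bps[b - 1], bps[b2])
            # structure indices of this sub-range within the token
            if orient > 0:
                p1, p2 = pos + (b - lo), pos + (b2 - lo)
            else:
                p1, p2 = pos + (hi - b2), pos + (hi - b)
            if dup:
                nb_blocks = {structure[p][0]
                             for p in (p1 - 1, p2 + 1)
                             if 0 <= p < len(structure)}
                if nb_blocks & set(range(b, b2 + 1)):
                    edits.append(Edit("DUP_TANDEM", *interval,
                                      inverted=orient < 0))
                else:
                    ip = _insertion_point(structure, tokens, pos, bps)
                    edits.append(Edit("DUP_DISPERSED", *interval,
                                      insert_point=ip, inverted=orient < 0))
            else:
                ip = _insertion_point(structure, tokens, pos, bps)
                edits.append(Edit("TRA", *interval, insert_point=ip,
                                  inverted=orient < 0))
            b = b2 + 1
    edits.sort(key=lambda e: (e.start, e.end, e.kind))
    return edits


def _insertion_point(structure, tokens, pos, bps):
    """Reference coordinate where the token at structure position *pos* was
    inserted: the exit coordinate of the preceding token (or the cluster
    start)."""
    prev = None
    for lo, hi, orient, p in tokens:
        if p < pos and (prev is None or p > prev[3]):
            prev = (lo, hi, orient, p)
    if prev is None:
        return bps[0]
    lo, hi, orient, _ = prev
    return bps[hi] if orient > 0 else bps[lo - 1]


def _edit_kind_class(e: Edit) -> set[str]:
    if e.kind == "DEL":
        return {"DEL"}
    if e.kind in ("DUP_TANDEM", "DUP_DISPERSED"):
        return {"DUP", "INV"} if e.inverted else {"DUP"}
    if e.kind == "INV":
        return {"INV"}
    return {"TRA"}


def classify_structure(allele_a: Structure, allele_b: Structure,
                       chrom: str, bps: list[int],
                       score: float = 0.0) -> list[SVCall]:
    """Classify a converged diploid structure into SV calls.

    Identical reference alleles yield an empty list.  One distinct edit kind
    in the cluster yields one call per edit (genotype hom when the edit is
    on both alleles); co-occurring kinds collapse into a single CSV call
    spanning the cluster, subtyped by the sorted kind set.
    """
    ref = reference_structure(len(bps) - 1)
    if allele_a == ref and allele_b == ref:
        return []
    ea = allele_edits(allele_a, bps)
    eb = allele_edits(allele_b, bps)
    sa, sb = structure_to_string(allele_a), structure_to_string(allele_b)
    kinds = set()
    for e in ea + eb:
        kinds |= _edit_kind_class(e)
    common = {e.key() for e in ea} & {e.key() for e in eb}
    base = dict(chrom=chrom, allele_a=sa, allele_b=sb, score=score,
                bps=list(bps))
    if len(kinds) <= 1:
        calls = []
        emitted = set()
        for e in ea + eb:
            if e.key() in emitted:
                continue
            emitted.add(e.key())
            gt = "hom" if e.key() in common else "het"
            calls.append(SVCall(e.kind, start=e.start, end=e.end, genotype=gt,
                                insert_point=e.insert_point, edits=[e], **base))
        calls.sort(key=lambda c: (c.start, c.end))
        return calls
    subtype = CSV_SUBTYPES.get(frozenset(kinds), "other")
    gt = "hom" if (allele_a == allele_b
                   or {e.key() for e in ea} == {e.key() for e in eb}) else "het"
    return [SVCall("CSV", start=bps[0], end=bps[-1], genotype=gt,
                   csv_subtype=subtype, edits=ea + eb, **base)]


# ---------------------------------------------------------------------------
# VCF output
# ---------------------------------------------------------------------------

_VCF_HEADER = """\
##fileformat=VCFv4.1
##source=svresolve
##INFO=<ID=SVTYPE,Number=1,Type=String,Description="Type of structural variant">
##INFO=<ID=END,Number=1,Type=Integer,Description="End position of the variant">
##INFO=<ID=SVLEN,Number=1,Type=Integer,Description="Difference in length between REF and ALT alleles">
##INFO=<ID=CSVTYPE,Number=1,Type=String,Description="Complex event subtype">
##INFO=<ID=BLOCKS,Number=1,Type=String,Description="Allele block structures as alleleA/alleleB">
##INFO=<ID=MATEID,Number=1,Type=String,Description="ID of mate breakend">
##ALT=<ID=DEL,Description="Deletion">
##ALT=<ID=DUP,Description="Duplication">
##ALT=<ID=INV,Description="Inversion">
##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">
"""

_SYMBOLIC = {"DEL": "DEL", "DUP_TANDEM": "DUP", "INV": "INV"}


def write_vcf(calls: list[SVCall], reference: str, sample_name: str,
              path: str) -> str:
    """Write calls as VCFv4.1.  Calls must be coordinate-sorted."""
    order = [(c.chrom, c.start) for c in calls]
    if order != sorted(order):
        raise ValueError("calls must be sorted by coordinate before writing VCF")
    fa = Fasta(reference, as_raw=True)
    lines = [_VCF_HEADER]
    for chrom in fa.keys():
        lines.append(f"##contig=<ID={chrom},length={len(fa[chrom])}>\n")
    lines.append("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
                 f"{sample_name}\n")
    gt_map = {"hom": "1/1", "het": "0/1"}
    counter = 0
    for c in calls:
        counter += 1
        vid = f"SV{counter}"
        gt = gt_map[c.genotype]
        blocks = f"{c.allele_a}/{c.allele_b}"
        ref_base = str(fa[c.chrom][max(0, c.start - 1):c.start]) or "N"
        if c.type in _SYMBOLIC:
            svtype = _SYMBOLIC[c.type]
            svlen = (c.end - c.start) * (-1 if c.type == "DEL" else 1)
            info = (f"SVTYPE={svtype};END={c.end};SVLEN={svlen};"
                    f"BLOCKS={blocks}")
            lines.append(f"{c.chrom}\t{c.start}\t{vid}\t{ref_base}\t"
                         f"<{svtype}>\t.\tPASS\t{info}\tGT\t{gt}\n")
        else:
            # breakend pair at the (first) novel adjacency
            p1 = c.start
            p2 = c.insert_point if c.insert_point is not None else c.end
            lo, hi = sorted((p1, p2))
            b1 = str(fa[c.chrom][lo:lo + 1]) or "N"
            b2 = str(fa[c.chrom][hi:hi + 1]) or "N"
            extra = f";CSVTYPE={c.csv_subtype}" if c.type == "CSV" else ""
            info1 = (f"SVTYPE=BND;MATEID={vid}_2;BLOCKS={blocks}{extra}")
            info2 = (f"SVTYPE=BND;MATEID={vid}_1;BLOCKS={blocks}{extra}")
            alt1 = f"{b1}[{c.chrom}:{hi + 1}["
            alt2 = f"]{c.chrom}:{lo + 1}]{b2}"
            lines.append(f"{c.chrom}\t{lo + 1}\t{vid}_1\t{b1}\t{alt1}\t.\t"
                         f"PASS\t{info1}\tGT\t{gt}\n")
            lines.append(f"{c.chrom}\t{hi + 1}\t{vid}_2\t{b2}\t{alt2}\t.\t"
                         f"PASS\t{info2}\tGT\t{gt}\n")
    with open(path, "w") as fh:
        fh.writelines(lines)
    return path


# ---------------------------------------------------------------------------
# Custom format
# ---------------------------------------------------------------------------

CUSTOM_HEADER = "#chrom\tbreakpoints\tallele_a\tallele_b\tscore\n"


def write_custom(records, path: str) -> str:
    """One line per cluster: chrom, breakpoint list, both allele structure
    strings, score.  *records* are SVCall-bearing clusters or plain tuples
    (chrom, bps, allele_a, allele_b, score)."""
    with open(path, "w") as fh:
        fh.write(CUSTOM_HEADER)
        for r in records:
            if isinstance(r, SVCall):
                chrom, bps, a, b, score = r.chrom, r.bps, r.allele_a, r.allele_b, r.score
            else:
                chrom, bps, a, b, score = r
            bp_str = ",".join(str(p) for p in bps)
            fh.write(f"{chrom}\t{bp_str}\t{a or '-'}\t{b or '-'}\t{score}\n")
    return path


def parse_custom(path: str):
    """Read the custom format back: (chrom, bps, allele_a, allele_b, score)."""
    out = []
    with open(path) as fh:
        for line in fh:
            if line.startswith("#") or not line.strip():
                continue
            chrom, bp_str, a, b, score = line.rstrip("\n").split("\t")
            out.append((chrom, [int(x) for x in bp_str.split(",")],
                        a, b, float(score)))
    return out
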