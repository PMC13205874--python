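"""Anchor-based haplotype comparison and SyRI-style region classification.

The caller finds k-mers that occur exactly once in each assembly (counting
both strands), chains co-linear anchors greedily, selects a syntenic
backbone per chromosome by weighted longest-increasing-subsequence, labels
the remaining chains INV/TRANS, and classifies the sequence between
consecutive backbone anchors into SNP / INS / DEL / HDR calls (or absorbs
it into the flanking syntenic block).  Sequence outside all chains becomes
NOTAL (haplotype-unique).  The resulting call set covers every base of both
haplotypes exactly once (SNP calls are positional annotations inside SYN
blocks and do not count toward coverage).
"""

from __future__ import annotations

from collections import namedtuple
from dataclasses import dataclass, field

import edlib
import numpy as np

from .models import HaplotypeGenome, RegionCall, sort_calls

Anchor = namedtuple("Anchor", "ref_chrom ref_pos qry_chrom qry_pos length orientation")

_CODE = np.full(256, 255, dtype=np.uint8)
for i, b in enumerate("ACGT"):
    _CODE[ord(b)] = i
_CODE[ord("N")] = 254


class ParameterError(ValueError):
    pass


class ConsistencyError(RuntimeError):
    """Internal inconsistency (e.g. overlapping backbone chains)."""


# ---------------------------------------------------------------------------
# anchors


def _kmer_codes(seq: str, k: int):
    """2-bit packed forward and reverse-complement codes for every k-mer.

    Returns (canonical_code, fwd_is_canonical, valid_mask) arrays of length
    len(seq) - k + 1; positions whose window contains N are invalid.
    """
    arr = _CODE[np.frombuffer(seq.encode(), dtype=np.uint8)]
    n = len(arr) - k + 1
    if n <= 0:
        z = np.zeros(0, dtype=np.uint64)
        return z, np.zeros(0, bool), np.zeros(0, bool)
    isn = (arr >= 200).astype(np.int32)
    cs = np.concatenate(([0], np.cumsum(isn)))
    valid = (cs[k:] - cs[:-k]) == 0
    base = np.where(arr >= 200, 0, arr).astype(np.uint64)
    fwd = np.zeros(n, dtype=np.uint64)
    rc = np.zeros(n, dtype=np.uint64)
    comp = np.uint64(3) - base
    four = np.uint64(4)
    for j in range(k):
        fwd = fwd * four + base[j : j + n]
        rc = rc + (comp[j : j + n] << np.uint64(2 * j))
    canon = np.minimum(fwd, rc)
    return canon, fwd <= rc, valid


def _genome_kmers(genome: HaplotypeGenome, k: int):
    codes, poss, chroms, strands = [], [], [], []
    chrom_ids = list(genome.chromosomes)
    for ci, cid in enumerate(chrom_ids):
        canon, fwd_canon, valid = _kmer_codes(genome.chromosomes[cid], k)
        idx = np.flatnonzero(valid)
        codes.append(canon[idx])
        poss.append(idx.astype(np.int64))
        chroms.append(np.full(idx.size, ci, dtype=np.int32))
        strands.append(fwd_canon[idx])
    code = np.concatenate(codes) if codes else np.zeros(0, np.uint64)
    return (
        chrom_ids,
        code,
        np.concatenate(poss) if poss else np.zeros(0, np.int64),
        np.concatenate(chroms) if chroms else np.zeros(0, np.int32),
        np.concatenate(strands) if strands else np.zeros(0, bool),
    )


def _unique_kmers(code, pos, chrom, strand):
    order = np.argsort(code, kind="stable")
    sc = code[order]
    # runs of identical codes
    is_new = np.concatenate(([True], sc[1:] != sc[:-1]))
    run_id = np.cumsum(is_new) - 1
    counts = np.bincount(run_id)
    unique_mask = counts[run_id] == 1
    keep = order[unique_mask]
    return code[keep], pos[keep], chrom[keep], strand[keep]


@dataclass
class AnchorSet:
    """Positioned unique-k-mer matches between the two assemblies.

    Array-backed for speed; iteration yields :class:`Anchor` tuples with
    chromosome names.  Sorted by (ref chromosome, ref position).
    """

    k: int
    ref_chroms: list[str]
    qry_chroms: list[str]
    ref_chrom_idx: np.ndarray
    ref_pos: np.ndarray
    qry_chrom_idx: np.ndarray
    qry_pos: np.ndarray
    forward: np.ndarray  # orientation per anchor

    def __len__(self) -> int:
        return self.ref_pos.size

    def __getitem__(self, i: int) -> Anchor:
        return Anchor(
            self.ref_chroms[self.ref_chrom_idx[i]],
            int(self.ref_pos[i]),
            self.qry_chroms[self.qry_chrom_idx[i]],
            int(self.qry_pos[i]),
            self.k,
            "forward" if self.forward[i] else "reverse",
        )

    def __iter__(self):
        for i in range(len(self)):
            yield self[i]


def find_anchors(ref: HaplotypeGenome, qry: HaplotypeGenome, k: int = 31) -> AnchorSet:
    """All k-mers occurring exactly once in each genome, as positioned anchors.

    Counting is strand-canonical (a k-mer and its reverse complement are one
    object); orientation records whether the match is forward or
    reverse-complement.  Anchors never span an N.
    """
    if not (11 <= k <= 63) or k % 2 == 0:
        raise ParameterError(f"k must be odd and in [11, 63], got {k}")
    if k > 31:
        raise ParameterError("k > 31 exceeds the 2-bit packing width; use k <= 31")
    r_ids, rc_, rp_, rch_, rs_ = _genome_kmers(ref, k)
    q_ids, qc_, qp_, qch_, qs_ = _genome_kmers(qry, k)
    rcode, rpos, rchrom, rstrand = _unique_kmers(rc_, rp_, rch_, rs_)
    qcode, qpos, qchrom, qstrand = _unique_kmers(qc_, qp_, qch_, qs_)
    ro = np.argsort(rcode, kind="stable")
    qo = np.argsort(qcode, kind="stable")
    rcode, rpos, rchrom, rstrand = rcode[ro], rpos[ro], rchrom[ro], rstrand[ro]
    qcode, qpos, qchrom, qstrand = qcode[qo], qpos[qo], qchrom[qo], qstrand[qo]
    idx = np.searchsorted(qcode, rcode)
    idx_c = np.clip(idx, 0, max(qcode.size - 1, 0))
    common = (qcode.size > 0) & (idx < qcode.size)
    match = np.zeros(rcode.size, dtype=bool)
    if qcode.size:
        match = common & (qcode[idx_c] == rcode)
    ri = np.flatnonzero(match)
    qi = idx[ri]
    order = np.lexsort((rpos[ri], rchrom[ri]))
    ri, qi = ri[order], qi[order]
    return AnchorSet(
        k=k,
        ref_chroms=r_ids,
        qry_chroms=q_ids,
        ref_chrom_idx=rchrom[ri],
        ref_pos=rpos[ri],
        qry_chrom_idx=qchrom[qi],
        qry_pos=qpos[qi],
        forward=rstrand[ri] == qstrand[qi],
    )


# ---------------------------------------------------------------------------
# chaining


@dataclass
class Chain:
    """A run of co-directional, co-chromosomal anchors."""

    anchors: AnchorSet
    start: int  # index range into the anchor arrays
    stop: int

    @property
    def n_anchors(self) -> int:
        return self.stop - self.start

    @property
    def k(self) -> int:
        return self.anchors.k

    @property
    def forward(self) -> bool:
        return bool(self.anchors.forward[self.start])

    @property
    def ref_chrom(self) -> str:
        return self.anchors.ref_chroms[self.anchors.ref_chrom_idx[self.start]]

    @property
    def qry_chrom(self) -> str:
        return self.anchors.qry_chroms[self.anchors.qry_chrom_idx[self.start]]

    @property
    def ref_span(self) -> tuple[int, int]:
        rp = self.anchors.ref_pos[self.start : self.stop]
        return int(rp[0]), int(rp[-1]) + self.k

    @property
    def qry_span(self) -> tuple[int, int]:
        qp = self.anchors.qry_pos[self.start : self.stop]
        return int(qp.min()), int(qp.max()) + self.k

    def ref_positions(self) -> np.ndarray:
        return self.anchors.ref_pos[self.start : self.stop]

    def qry_positions(self) -> np.ndarray:
        return self.anchors.qry_pos[self.start : self.stop]


def chain_anchors(
    anchors: AnchorSet, max_gap: int = 20_000, min_chain_anchors: int = 3
) -> list[Chain]:
    """Greedy chaining in ref order.

    A chain breaks when the chromosome pair, orientation, qry monotonicity
    (increasing for forward, decreasing for reverse chains) or the gap
    bound on either genome is violated.  Chains with fewer than
    ``min_chain_anchors`` anchors are discarded.
    """
    n = len(anchors)
    if n == 0:
        return []
    rc, rp = anchors.ref_chrom_idx, anchors.ref_pos
    qc, qp = anchors.qry_chrom_idx, anchors.qry_pos
    fwd = anchors.forward
    k = anchors.k
    brk = (
        (rc[1:] != rc[:-1])
        | (qc[1:] != qc[:-1])
        | (fwd[1:] != fwd[:-1])
        | (rp[1:] - (rp[:-1] + k) > max_gap)
        | np.where(
            fwd[:-1],
            (qp[1:] <= qp[:-1]) | (qp[1:] - (qp[:-1] + k) > max_gap),
            (qp[1:] >= qp[:-1]) | (qp[:-1] - (qp[1:] + k) > max_gap),
        )
    )
    bounds = np.concatenate(([0], np.flatnonzero(brk) + 1, [n]))
    chains = [
        Chain(anchors, int(a), int(b))
        for a, b in zip(bounds[:-1], bounds[1:])
        if b - a >= min_chain_anchors
    ]
    return chains


# ---------------------------------------------------------------------------
# classification


def _weighted_lis(chains: list[Chain], slack: int = 0) -> list[int]:
    """Indices of the max-weight subset with increasing qry spans (O(m^2)).

    ``slack`` tolerates small span overlaps from coincidental junction
    anchors at chain boundaries.
    """
    m = len(chains)
    if m == 0:
        return []
    w = [c.ref_span[1] - c.ref_span[0] for c in chains]
    best = list(w)
    prev = [-1] * m
    for i in range(m):
        qi = chains[i].qry_span
        for j in range(i):
            qj = chains[j].qry_span
            if qj[1] <= qi[0] + slack and best[j] + w[i] > best[i]:
                best[i] = best[j] + w[i]
                prev[i] = j
    i = int(np.argmax(best))
    out = []
    while i != -1:
        out.append(i)
        i = prev[i]
    return out[::-1]


class _Emitter:
    """Accumulates calls while tracking the open syntenic block."""

    def __init__(self, ref_chrom: str, qry_chrom: str):
        self.ref_chrom = ref_chrom
        self.qry_chrom = qry_chrom
        self.calls: list[RegionCall] = []
        self.syn_r: int | None = None
        self.syn_q: int | None = None

    def open_syn(self, r: int, q: int) -> None:
        if self.syn_r is None:
            self.syn_r, self.syn_q = r, q

    def close_syn(self, r: int, q: int) -> None:
        if self.syn_r is not None and (r > self.syn_r or q > self.syn_q):
            self.calls.append(RegionCall(
                "SYN", ref_chrom=self.ref_chrom, ref_start=self.syn_r, ref_end=r,
                qry_chrom=self.qry_chrom, qry_start=self.syn_q, qry_end=q,
            ))
        self.syn_r = self.syn_q = None

    def snp(self, r: int, q: int, rb: str, qb: str) -> None:
        self.calls.append(RegionCall(
            "SNP", ref_chrom=self.ref_chrom, ref_start=r, ref_end=r + 1,
            qry_chrom=self.qry_chrom, qry_start=q, qry_end=q + 1,
            ref_base=rb, qry_base=qb,
        ))

    def call(self, rtype: str, r0: int, r1: int, q0: int, q1: int) -> None:
        self.close_syn(r0, q0)
        self.calls.append(RegionCall(
            rtype, ref_chrom=self.ref_chrom, ref_start=r0, ref_end=r1,
            qry_chrom=self.qry_chrom, qry_start=q0, qry_end=q1,
        ))
        self.open_syn(r1, q1)


def _parse_cigar(cigar: str):
    num = ""
    for ch in cigar:
        if ch.isdigit():
            num += ch
        else:
            yield int(num), ch
            num = ""


def _classify_pair(
    em: _Emitter,
    rseq: str,
    qseq: str,
    r0: int,
    r1: int,
    q0: int,
    q1: int,
    min_sv_len: int,
    hdr_min_len: int,
    hdr_max_identity: float,
) -> None:
    """Classify one inter-anchor gap pair (internal coordinates)."""
    lr, lq = r1 - r0, q1 - q0
    # adjacent anchors may overlap on one genome when the junction is not
    # left-aligned (indel inside a short repeat): the overlapped bases are
    # already inside the flanking anchors, so clamp that side to empty
    if lr <= 0 and lq <= 0:
        return
    if lq <= 0:
        em.call("DEL", r0, r1, q0, q0)
        return
    if lr <= 0:
        em.call("INS", r0, r0, q0, q1)
        return
    a = rseq[r0:r1]
    b = qseq[q0:q1]
    if lr >= hdr_min_len and lq >= hdr_min_len:
        limit = int((1.0 - hdr_max_identity) * max(lr, lq))
        res = edlib.align(a, b, mode="NW", task="path", k=limit)
        if res["editDistance"] == -1:
            em.call("HDR", r0, r1, q0, q1)
            return
        # identity >= threshold: absorb into SYN, re-calling interior variants
        _absorb_alignment(em, a, b, r0, q0, res["cigar"])
        return
    if lr == lq:
        # positional comparison: equal-length gaps are runs of substitutions
        # (an optimal-path aligner can swap adjacent mismatches for a
        # spurious indel pair, shifting SNP positions)
        for i in range(lr):
            if a[i] != b[i]:
                em.snp(r0 + i, q0 + i, a[i], b[i])
        return
    # unequal gap: end-anchored comparison.  Trim the exact common prefix
    # and suffix, then emit the remainder.
    m = min(lr, lq)
    p = 0
    while p < m and a[p] == b[p]:
        p += 1
    s = 0
    while s < m - p and a[lr - 1 - s] == b[lq - 1 - s]:
        s += 1
    ra, rb = lr - p - s, lq - p - s
    ar0, aq0 = r0 + p, q0 + p
    if ra == 0:
        em.call("INS", ar0, ar0, aq0, aq0 + rb)
        return
    if rb == 0:
        em.call("DEL", ar0, ar0 + ra, aq0, aq0)
        return
    if ra == rb:
        for i in range(ra):
            if a[p + i] != b[p + i]:
                em.snp(ar0 + i, aq0 + i, a[p + i], b[p + i])
        return
    # a single indel plus nearby substitutions (which push the flanking
    # anchors outward) is the common case: test both end-anchorings of the
    # short side before resorting to a global alignment, which would
    # scatter a grossly one-sided remainder into spurious 1-bp matches
    m2 = min(ra, rb)
    diff = abs(ra - rb)
    aa = a[p : lr - s]
    bb = b[p : lq - s]
    short, long_ = (aa, bb) if ra < rb else (bb, aa)
    mism_start = sum(short[i] != long_[i] for i in range(m2))
    mism_end = sum(short[m2 - 1 - i] != long_[-1 - i] for i in range(m2))
    if min(mism_start, mism_end) <= max(2.0, 0.3 * m2):
        if mism_end <= mism_start:
            # indel first, then aligned columns
            if ra > rb:
                em.call("DEL", ar0, ar0 + diff, aq0, aq0)
            else:
                em.call("INS", ar0, ar0, aq0, aq0 + diff)
            roff = ar0 + (diff if ra > rb else 0)
            qoff = aq0 + (diff if rb > ra else 0)
            for i in range(m2):
                ca, cb = aa[-m2 + i], bb[-m2 + i]
                if ca != cb:
                    em.snp(roff + i, qoff + i, ca, cb)
        else:
            for i in range(m2):
                if aa[i] != bb[i]:
                    em.snp(ar0 + i, aq0 + i, aa[i], bb[i])
            if ra > rb:
                em.call("DEL", ar0 + m2, ar0 + ra, aq0 + m2, aq0 + m2)
            else:
                em.call("INS", ar0 + m2, ar0 + m2, aq0 + m2, aq0 + rb)
        return
    res = edlib.align(aa, bb, mode="NW", task="path")
    _absorb_alignment(em, aa, bb, ar0, aq0, res["cigar"])


def _absorb_alignment(em: _Emitter, a: str, b: str, r0: int, q0: int, cigar: str) -> None:
    r, q = r0, q0
    for n, op in _parse_cigar(cigar):
        if op == "=":
            r += n
            q += n
        elif op == "X":
            for i in range(n):
                em.snp(r + i, q + i, a[r + i - r0], b[q + i - q0])
            r += n
            q += n
        elif op == "I":  # edlib: base in query (= ref/hap1) only
            em.call("DEL", r, r + n, q, q)
            r += n
        elif op == "D":  # edlib: base in target (= qry/hap2) only
            em.call("INS", r, r, q, q + n)
            q += n


def classify_regions(
    chains: list[Chain],
    ref: HaplotypeGenome,
    qry: HaplotypeGenome,
    min_sv_len: int = 50,
    hdr_min_len: int = 500,
    hdr_max_identity: float = 0.9,
) -> list[RegionCall]:
    """Produce the SyRI-style region partition from anchor chains.

    The longest consistent forward chain set per chromosome forms the SYN
    backbone; reverse chains to the backbone chromosome are INV, chains to
    other chromosomes (or out of backbone order) are TRANS.  Sequence
    between consecutive backbone anchors is classified SNP/INS/DEL/HDR or
    absorbed into SYN; sequence outside every call becomes NOTAL.
    """
    calls: list[RegionCall] = []
    by_ref: dict[str, list[Chain]] = {}
    for c in chains:
        by_ref.setdefault(c.ref_chrom, []).append(c)

    # ------- backbone selection and INV/TRANS labelling
    backbone: dict[str, list[Chain]] = {}
    extra: list[tuple[str, Chain]] = []  # (label, chain)
    for rchrom, cs in by_ref.items():
        fwd = [c for c in cs if c.forward]
        if not fwd:
            for c in cs:
                extra.append(("INV" if c.qry_chrom == rchrom else "TRANS", c))
            continue
        span_by_q: dict[str, int] = {}
        for c in fwd:
            span_by_q[c.qry_chrom] = span_by_q.get(c.qry_chrom, 0) + (
                c.ref_span[1] - c.ref_span[0]
            )
        best_q = max(span_by_q, key=span_by_q.get)
        cand = sorted(
            [c for c in fwd if c.qry_chrom == best_q], key=lambda c: c.ref_span
        )
        keep = set(_weighted_lis(cand, slack=cand[0].k if cand else 0))
        bb = [cand[i] for i in sorted(keep)]
        backbone[rchrom] = bb
        for i, c in enumerate(cand):
            if i not in keep:
                extra.append(("TRANS", c))
        for c in fwd:
            if c.qry_chrom != best_q:
                extra.append(("TRANS", c))
        for c in cs:
            if not c.forward:
                extra.append(("INV" if c.qry_chrom == best_q else "TRANS", c))

    # merged backbone anchor arrays per chromosome
    bb_rp: dict[str, np.ndarray] = {}
    bb_qp: dict[str, np.ndarray] = {}
    bb_qchrom: dict[str, str] = {}
    k = chains[0].k if chains else 31
    for rchrom, bb in backbone.items():
        rp_parts, qp_parts = [], []
        last_r = last_q = -1
        for c in bb:
            rp_c, qp_c = c.ref_positions(), c.qry_positions()
            # drop leading anchors that overlap the previous chain's tail
            # (coincidental junction anchors)
            ok = (rp_c > last_r) & (qp_c > last_q)
            if not ok.any():
                continue
            j = int(np.argmax(ok))
            rp_parts.append(rp_c[j:])
            qp_parts.append(qp_c[j:])
            last_r, last_q = int(rp_c[-1]), int(qp_c[-1])
        rp = np.concatenate(rp_parts)
        qp = np.concatenate(qp_parts)
        if np.any(np.diff(rp) <= 0) or np.any(np.diff(qp) <= 0):
            raise ConsistencyError(
                f"backbone chains overlap or disorder on {rchrom}"
            )
        bb_rp[rchrom], bb_qp[rchrom] = rp, qp
        bb_qchrom[rchrom] = bb[0].qry_chrom

    # emit INV/TRANS calls and index their excisions into backbone gaps.
    # A chain boundary anchor can coincidentally overlap a backbone anchor
    # by a few bases, so spans are located with tolerance k and clipped to
    # the gap they fall in.
    gap_events: dict[tuple[str, int], list[dict]] = {}

    def locate(axis_pos: np.ndarray, span: tuple[int, int], kk: int):
        """(gap index, clipped span) between anchors i-1 and i, or None."""
        i = int(np.searchsorted(axis_pos, span[0] + kk, side="right"))
        if i == 0 or i >= axis_pos.size:
            return None
        lo = int(axis_pos[i - 1]) + kk
        hi = int(axis_pos[i])
        if span[0] < lo - kk or span[1] > hi + kk:
            return None
        s, e = max(span[0], lo), min(span[1], hi)
        if s >= e:
            return None
        return i, (s, e)

    for label, c in extra:
        rs = c.ref_span
        qs = c.qry_span
        ref_loc = locate(bb_rp[c.ref_chrom], rs, c.k) if c.ref_chrom in bb_rp else None
        qry_loc = None
        for rchrom2, qp2 in bb_qp.items():
            if bb_qchrom[rchrom2] == c.qry_chrom:
                qry_loc = locate(qp2, qs, c.k)
                qry_home = rchrom2
                break
        if ref_loc is None or qry_loc is None:
            # chain outside (or straddling) the backbone: leave its sequence
            # to gap logic / NOTAL fill rather than double-covering it
            continue
        rs_c, qs_c = ref_loc[1], qry_loc[1]
        calls.append(RegionCall(
            label, ref_chrom=c.ref_chrom, ref_start=rs_c[0], ref_end=rs_c[1],
            qry_chrom=c.qry_chrom, qry_start=qs_c[0], qry_end=qs_c[1],
        ))
        if label == "INV" and qry_home == c.ref_chrom and qry_loc[0] == ref_loc[0]:
            gap_events.setdefault((c.ref_chrom, ref_loc[0]), []).append(
                {"ref": rs_c, "qry": qs_c}
            )
        else:
            gap_events.setdefault((c.ref_chrom, ref_loc[0]), []).append(
                {"ref": rs_c, "qry": None}
            )
            gap_events.setdefault((qry_home, qry_loc[0]), []).append(
                {"ref": None, "qry": qs_c}
            )

    # ------- walk backbone gaps
    for rchrom, rp in bb_rp.items():
        qchrom = bb_qchrom[rchrom]
        qp = bb_qp[rchrom]
        rseq = ref.chromosomes[rchrom]
        qseq = qry.chromosomes[qchrom]
        em = _Emitter(rchrom, qchrom)
        em.open_syn(int(rp[0]), int(qp[0]))
        for i in range(1, rp.size):
            r0, r1 = int(rp[i - 1]) + k, int(rp[i])
            q0, q1 = int(qp[i - 1]) + k, int(qp[i])
            evs = gap_events.get((rchrom, i), [])
            cur_r, cur_q = r0, q0
            for ev in sorted(evs, key=lambda e: e["ref"][0] if e["ref"] else e["qry"][0]):
                er = ev["ref"] if ev["ref"] is not None else (cur_r, cur_r)
                eq = ev["qry"] if ev["qry"] is not None else (cur_q, cur_q)
                _classify_pair(em, rseq, qseq, cur_r, er[0], cur_q, eq[0],
                               min_sv_len, hdr_min_len, hdr_max_identity)
                em.close_syn(er[0], eq[0])
                em.open_syn(er[1], eq[1])
                cur_r, cur_q = er[1], eq[1]
            _classify_pair(em, rseq, qseq, cur_r, r1, cur_q, q1,
                           min_sv_len, hdr_min_len, hdr_max_identity)
        em.close_syn(int(rp[-1]) + k, int(qp[-1]) + k)
        calls.extend(em.calls)

    # ------- NOTAL fill: complement of covered sequence on each haplotype
    for hap, genome in (("hap1", ref), ("hap2", qry)):
        for cid, seq in genome.chromosomes.items():
            cov = np.zeros(len(seq) + 1, dtype=np.int32)
            for c in calls:
                if c.rtype == "SNP":
                    continue
                iv = c.interval(hap)
                if iv is not None and iv[0] == cid:
                    cov[iv[1]] += 1
                    cov[iv[2]] -= 1
            depth = np.cumsum(cov[:-1])
            uncovered = depth == 0
            # N runs are not attributed to any region class
            edges = np.flatnonzero(np.diff(np.concatenate(
                ([0], uncovered.view(np.int8), [0])
            )))
            for s, e in zip(edges[::2], edges[1::2]):
                if hap == "hap1":
                    calls.append(RegionCall("NOTAL", ref_chrom=cid,
                                            ref_start=int(s), ref_end=int(e)))
                else:
                    calls.append(RegionCall("NOTAL", qry_chrom=cid,
                                            qry_start=int(s), qry_end=int(e)))
    return sort_calls(calls)


# ---------------------------------------------------------------------------
# partition audit


@dataclass
class PartitionReport:
    """Coverage audit of a call set over both haplotypes."""

    uncovered: dict[str, list[tuple[str, int, int]]] = field(default_factory=dict)
    overlapped: dict[str, list[tuple[str, int, int]]] = field(default_factory=dict)

    @property
    def ok(self) -> bool:
        return not any(self.uncovered.values()) and not any(self.overlapped.values())

    def total_uncovered(self, hap: str) -> int:
        return sum(e - s for _, s, e in self.uncovered.get(hap, []))

    def total_overlapped(self, hap: str) -> int:
        return sum(e - s for _, s, e in self.overlapped.get(hap, []))


def region_partition_check(
    calls: list[RegionCall], ref: HaplotypeGenome, qry: HaplotypeGenome
) -> PartitionReport:
    """Verify every non-N base of each haplotype is covered exactly once.

    SNP calls are positional annotations inside SYN blocks and are excluded
    from coverage counting.  Report-only: returns interval lists of
    uncovered and multiply-covered sequence (empty for a valid run).
    """
    report = PartitionReport(uncovered={"hap1": [], "hap2": []},
                             overlapped={"hap1": [], "hap2": []})
    for hap, genome in (("hap1", ref), ("hap2", qry)):
        for cid, seq in genome.chromosomes.items():
            cov = np.zeros(len(seq) + 1, dtype=np.int32)
            for c in calls:
                if c.rtype == "SNP":
                    continue
                iv = c.interval(hap)
                if iv is not None and iv[0] == cid:
                    cov[iv[1]] += 1
                    cov[iv[2]] -= 1
            depth = np.cumsum(cov[:-1])
            isn = np.frombuffer(seq.encode(), dtype=np.uint8) == ord("N")
            for kind, mask in (("uncovered", (depth == 0) & ~isn),
                               ("overlapped", depth > 1)):
                edges = np.flatnonzero(np.diff(np.concatenate(
                    ([0], mask.view(np.int8), [0])
                )))
                for s, e in zip(edges[::2], edges[1::2]):
                    getattr(report, kind)[hap].append((cid, int(s), int(e)))
    return report
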