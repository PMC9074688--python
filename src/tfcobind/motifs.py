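"""Consensus and PWM motif scanning with shuffled-background enrichment.

Consensus scanning honours IUPAC degeneracy on both strands. PWM scoring is
log2 odds against a background base composition; probabilities come from site
counts with a per-base pseudocount alpha: p_b = (count_b + 4*alpha*bg_b) /
(n_sites + 4*alpha). Enrichment compares the observed hit count against
per-sequence dinucleotide-preserving shuffles (Altschul-Erickson Euler-path
shuffle), so the null keeps each sequence's dinucleotide composition.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

__all__ = [
    "MotifModel",
    "MotifHit",
    "scan_consensus",
    "scan_pwm",
    "scan",
    "mutate_and_rescan",
    "motif_enrichment",
    "dinucleotide_shuffle",
    "reverse_complement",
    "IUPAC",
]

IUPAC: dict[str, frozenset[str]] = {
    "A": frozenset("A"),
    "C": frozenset("C"),
    "G": frozenset("G"),
    "T": frozenset("T"),
    "R": frozenset("AG"),
    "Y": frozenset("CT"),
    "S": frozenset("CG"),
    "W": frozenset("AT"),
    "K": frozenset("GT"),
    "M": frozenset("AC"),
    "B": frozenset("CGT"),
    "D": frozenset("AGT"),
    "H": frozenset("ACT"),
    "V": frozenset("ACG"),
    "N": frozenset("ACGT"),
}

_COMPLEMENT = str.maketrans("ACGTRYSWKMBDHVN", "TGCAYRSWMKVHDBN")
_BASES = "ACGT"
_BASE_INDEX = {b: i for i, b in enumerate(_BASES)}


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


def _validate_dna(seq: str) -> str:
    seq = seq.upper()
    bad = set(seq) - set("ACGTN")
    if bad:
        raise ValueError(f"invalid characters in sequence: {sorted(bad)}")
    return seq


@dataclass
class MotifModel:
    """A motif as an IUPAC consensus and/or a position weight matrix.

    The PWM is stored as a 4 x L probability matrix (rows A, C, G, T).
    score_threshold is in bits (log2-odds against the background).
    """

    name: str
    consensus: Optional[str] = None
    pwm: Optional[np.ndarray] = None
    background: np.ndarray = field(default_factory=lambda: np.full(4, 0.25))
    score_threshold: float = 0.0

    def __post_init__(self) -> None:
        if self.consensus is None and self.pwm is None:
            raise ValueError("motif needs a consensus or a PWM")
        if self.consensus is not None:
            self.consensus = self.consensus.upper()
            bad = set(self.consensus) - set(IUPAC)
            if bad:
                raise ValueError(f"consensus uses non-IUPAC codes: {sorted(bad)}")
        if self.pwm is not None:
            self.pwm = np.asarray(self.pwm, dtype=float)
            if self.pwm.shape[0] != 4:
                raise ValueError("PWM must be 4 x L (rows A, C, G, T)")
            self.pwm = self.pwm / self.pwm.sum(axis=0, keepdims=True)
        self.background = np.asarray(self.background, dtype=float)
        self.background = self.background / self.background.sum()

    @property
    def length(self) -> int:
        if self.pwm is not None:
            return self.pwm.shape[1]
        return len(self.consensus)

    @classmethod
    def from_sites(
        cls,
        name: str,
        sites: Sequence[str],
        alpha: float = 1.0,
        background: Optional[Sequence[float]] = None,
        score_threshold: float = 0.0,
    ) -> "MotifModel":
        """Build a PWM from aligned binding sites with per-base pseudocount alpha."""
        if not sites:
            raise ValueError("need at least one site")
        L = len(sites[0])
        if any(len(s) != L for s in sites):
            raise ValueError("sites must share one length")
        bg = np.full(4, 0.25) if background is None else np.asarray(background, float)
        bg = bg / bg.sum()
        counts = np.zeros((4, L))
        for s in sites:
            s = _validate_dna(s)
            for j, c in enumerate(s):
                counts[_BASE_INDEX[c], j] += 1
        probs = (counts + 4 * alpha * bg[:, None]) / (len(sites) + 4 * alpha)
        return cls(name=name, pwm=probs, background=bg, score_threshold=score_threshold)

    @classmethod
    def from_consensus_as_pwm(cls, name: str, consensus: str, score_threshold: float = 0.0) -> "MotifModel":
        """Degenerate PWM sharing probability uniformly over each code's bases."""
        consensus = consensus.upper()
        pwm = np.zeros((4, len(consensus)))
        for j, code in enumerate(consensus):
            allowed = IUPAC[code]
            for b in allowed:
                pwm[_BASE_INDEX[b], j] = 1.0 / len(allowed)
        return cls(name=name, consensus=consensus, pwm=pwm, score_threshold=score_threshold)

    def max_score(self) -> float:
        if self.pwm is None:
            raise ValueError("no PWM set")
        with np.errstate(divide="ignore"):
            odds = np.log2(self.pwm / self.background[:, None])
        return float(odds.max(axis=0).sum())


@dataclass(frozen=True, order=True)
class MotifHit:
    sequence_id: str
    offset: int  # 0-based, on the forward strand of the scanned sequence
    strand: str
    score: float
    matched: str  # forward-strand substring at the hit


def _consensus_matches(window: str, consensus: str) -> bool:
    for c, code in zip(window, consensus):
        if c == "N":
            if code != "N":
                return False
        elif c not in IUPAC[code]:
            return False
    return True


def scan_consensus(seq: str, motif: MotifModel, sequence_id: str = "seq") -> list[MotifHit]:
    """All matches of the IUPAC consensus on both strands.

    An N in the sequence matches only the consensus code N. Offsets refer to
    the forward strand; `matched` is the forward-strand substring.
    """
    if motif.consensus is None:
        raise ValueError("motif has no consensus")
    seq = _validate_dna(seq)
    cons = motif.consensus
    L = len(cons)
    rc_cons = reverse_complement(cons)
    hits: list[MotifHit] = []
    for off in range(0, len(seq) - L + 1):
        window = seq[off : off + L]
        if _consensus_matches(window, cons):
            hits.append(MotifHit(sequence_id, off, "+", float(L), window))
        if _consensus_matches(window, rc_cons):
            hits.append(MotifHit(sequence_id, off, "-", float(L), window))
    return hits


def _encode(seq: str) -> np.ndarray:
    arr = np.frombuffer(seq.encode(), dtype=np.uint8)
    out = np.full(arr.shape, -1, dtype=np.int64)
    for b, i in _BASE_INDEX.items():
        out[arr == ord(b)] = i
    return out


def _pwm_scores(enc: np.ndarray, odds: np.ndarray) -> np.ndarray:
    """Window scores; windows containing N (code -1) score -inf."""
    L = odds.shape[1]
    n_win = enc.size - L + 1
    if n_win <= 0:
        return np.empty(0)
    scores = np.zeros(n_win)
    valid = np.ones(n_win, dtype=bool)
    for j in range(L):
        col = enc[j : j + n_win]
        ok = col >= 0
        valid &= ok
        scores += np.where(ok, odds[np.clip(col, 0, 3), j], 0.0)
    scores[~valid] = -np.inf
    return scores


def scan_pwm(seq: str, motif: MotifModel, sequence_id: str = "seq") -> list[MotifHit]:
    """Log2-odds PWM scan of both strands; hits where score >= score_threshold."""
    if motif.pwm is None:
        raise ValueError("motif has no PWM")
    seq = _validate_dna(seq)
    L = motif.length
    if L > len(seq):
        return []
    with np.errstate(divide="ignore"):
        odds = np.log2(motif.pwm / motif.background[:, None])
    enc = _encode(seq)
    hits: list[MotifHit] = []
    fwd = _pwm_scores(enc, odds)
    for off in np.nonzero(fwd >= motif.score_threshold)[0]:
        hits.append(MotifHit(sequence_id, int(off), "+", float(fwd[off]), seq[off : off + L]))
    rc = reverse_complement(seq)
    rev = _pwm_scores(_encode(rc), odds)
    n = len(seq)
    for off_rc in np.nonzero(rev >= motif.score_threshold)[0]:
        off = n - L - int(off_rc)
        hits.append(MotifHit(sequence_id, off, "-", float(rev[off_rc]), seq[off : off + L]))
    return sorted(hits)


def scan(seq: str, motif: MotifModel, sequence_id: str = "seq") -> list[MotifHit]:
    """Consensus scan when the motif has a consensus, PWM scan otherwise."""
    if motif.consensus is not None:
        return scan_consensus(seq, motif, sequence_id)
    return scan_pwm(seq, motif, sequence_id)


def mutate_and_rescan(
    seq: str,
    edits: Sequence[tuple[int, str, str]],
    motif: MotifModel,
) -> dict:
    """Apply substitutions (position, old, new) and report the hit-set change.

    Positions are 0-based on the input sequence and must match `old` exactly
    (guards against coordinate-convention slips). Replacement lengths may
    differ; downstream coordinates shift accordingly. Destroyed/created hits
    are computed after mapping pre-edit hit offsets through the length shifts.
    """
    seq = _validate_dna(seq)
    for pos, old, _new in edits:
        found = seq[pos : pos + len(old)]
        if found != old.upper():
            raise ValueError(
                f"edit at position {pos}: expected {old.upper()!r}, found {found!r}"
            )
    ordered = sorted(edits, key=lambda e: e[0])
    for (p1, o1, _), (p2, _o2, _2) in zip(ordered, ordered[1:]):
        if p1 + len(o1) > p2:
            raise ValueError("overlapping edits")
    out = []
    cursor = 0
    shifts: list[tuple[int, int]] = []  # (original position after edit, cumulative shift)
    shift = 0
    for pos, old, new in ordered:
        out.append(seq[cursor:pos])
        out.append(new.upper())
        cursor = pos + len(old)
        shift += len(new) - len(old)
        shifts.append((cursor, shift))
    out.append(seq[cursor:])
    mutated = _validate_dna("".join(out))

    def map_offset(off: int) -> int:
        s = 0
        for boundary, cum in shifts:
            if off >= boundary:
                s = cum
        return off + s

    before = scan(seq, motif)
    after = scan(mutated, motif)
    after_keys = {(h.offset, h.strand, h.matched) for h in after}
    before_keys_mapped = {(map_offset(h.offset), h.strand, h.matched) for h in before}
    destroyed = [h for h in before if (map_offset(h.offset), h.strand, h.matched) not in after_keys]
    created = [h for h in after if (h.offset, h.strand, h.matched) not in before_keys_mapped]
    return {
        "sequence": mutated,
        "hits_before": before,
        "hits_after": after,
        "destroyed": destroyed,
        "created": created,
    }


def dinucleotide_shuffle(seq: str, rng: np.random.Generator) -> str:
    """Altschul-Erickson shuffle preserving the dinucleotide multiset.

    Picks a random last-exit edge per vertex until the last-edge graph is
    connected to the terminal character, then shuffles the remaining edges and
    walks the Euler path.
    """
    seq = _validate_dna(seq)
    if len(seq) < 3:
        return seq
    edges: dict[str, list[str]] = {}
    for a, b in zip(seq, seq[1:]):
        edges.setdefault(a, []).append(b)
    first, last = seq[0], seq[-1]
    vertices = list(edges)
    if len(vertices) == 1:
        return seq
    non_terminal = [v for v in vertices if v != last]
    for _attempt in range(10_000):
        last_edge = {v: edges[v][int(rng.integers(len(edges[v])))] for v in non_terminal}
        # connectivity: from every vertex, following last edges reaches `last`
        ok = True
        for v in non_terminal:
            seen = {v}
            cur = v
            while cur != last:
                nxt = last_edge.get(cur)
                if nxt is None or nxt in seen:
                    ok = False
                    break
                seen.add(nxt)
                cur = nxt
            if not ok:
                break
        if ok:
            break
    else:  # pragma: no cover - bounded retry exhausted
        return seq
    shuffled: dict[str, list[str]] = {}
    for v in vertices:
        rest = list(edges[v])
        if v in last_edge:
            rest.remove(last_edge[v])
        rng.shuffle(rest)
        if v in last_edge:
            rest.append(last_edge[v])
        shuffled[v] = rest
    out = [first]
    cur = first
    ptr = {v: 0 for v in vertices}
    for _ in range(len(seq) - 1):
        nxt = shuffled[cur][ptr[cur]]
        ptr[cur] += 1
        out.append(nxt)
        cur = nxt
    return "".join(out)


def motif_enrichment(
    seqs: Sequence[str],
    motif: MotifModel,
    n_shuffles: int = 100,
    seed: int = 0,
) -> dict:
    """Motif hit enrichment against a dinucleotide-preserving shuffled null.

    empirical_p = (1 + #{null >= observed}) / (n_shuffles + 1); its floor is
    therefore 1/(n_shuffles+1). Sequences shorter than the motif contribute
    zero hits.
    """
    if n_shuffles < 1:
        raise ValueError("n_shuffles must be >= 1")
    rng = np.random.default_rng(seed)
    seqs = [_validate_dna(s) for s in seqs]

    def count_hits(sequences: Sequence[str]) -> int:
        total = 0
        for i, s in enumerate(sequences):
            if len(s) < motif.length:
                continue
            total += len(scan(s, motif, sequence_id=f"seq{i}"))
        return total

    observed = count_hits(seqs)
    null = np.empty(n_shuffles)
    for k in range(n_shuffles):
        null[k] = count_hits([dinucleotide_shuffle(s, rng) for s in seqs])
    null_mean = float(null.mean())
    null_sd = float(null.std(ddof=1)) if n_shuffles > 1 else 0.0
    if null_sd > 0:
        z = (observed - null_mean) / null_sd
    else:
        z = 0.0 if observed == null_mean else float("inf") * np.sign(observed - null_mean)
    return {
        "observed": observed,
        "null_mean": null_mean,
        "null_sd": null_sd,
        "z": float(z),
        "empirical_p": float((1 + np.sum(null >= observed)) / (n_shuffles + 1)),
    }
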