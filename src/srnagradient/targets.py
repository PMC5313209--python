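"""Six-rule plant miRNA target prediction (Allen/Schwab-style).

A miRNA is slid along every transcript; each candidate site is aligned to
the miRNA (antiparallel, GU-aware, at most one single-nucleotide bulge)
and the duplex is judged by six criteria:

1. total mismatch score <= 4 (G:U wobbles count 0.5, gaps 1.0);
2. no run of more than two adjacent non-Watson-Crick positions;
3. no adjacent non-WC positions within miRNA positions 2-12;
4. positions 10-11 perfectly paired;
5. mismatch score over positions 1-12 <= 2.5;
6. duplex free energy at least 75% (in magnitude) of the energy of the
   miRNA bound to its perfect complement.

Positions are numbered 1-based from the miRNA 5' end.  In the
per-miRNA-position state vector a bulged *target* nucleotide is charged
as a GAP to the miRNA position immediately 3' of the bulge, so the score
identity  score = #MM + #GAP + 0.5*#GU  always holds.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

from .seqio import to_rna
from .thermo import duplex_mfe, pair_type, perfect_mfe

WC_PAIRS = {"AU", "UA", "CG", "GC"}
GU_PAIRS = {"GU", "UG"}

STATE_WEIGHT = {"WC": 0.0, "GU": 0.5, "MM": 1.0, "GAP": 1.0}


@dataclass
class TargetConfig:
    allow_gap: bool = True
    gu_in_runs: bool = True
    max_score: float = 4.0
    mfe_ratio_min: float = 0.75


@dataclass(frozen=True)
class DuplexAlignment:
    """miRNA 5'->3' vs target site 3'->5', one state per miRNA position."""

    mirna: str
    site: str  # 3'->5' relative to the miRNA
    states: tuple[str, ...]

    def __post_init__(self) -> None:
        if len(self.states) != len(self.mirna):
            raise ValueError("states length != miRNA length")
        for s in self.states:
            if s not in STATE_WEIGHT:
                raise ValueError(f"invalid state {s!r}")


@dataclass
class RuleVerdict:
    score: float
    rule1: bool
    rule2: bool
    rule3: bool
    rule4: bool
    rule5: bool
    rule6: bool
    mfe_duplex: float = 0.0
    mfe_perfect: float = 0.0
    mfe_ratio: float = 0.0

    @property
    def all_pass(self) -> bool:
        return (self.rule1 and self.rule2 and self.rule3
                and self.rule4 and self.rule5 and self.rule6)


@dataclass
class TargetHit:
    mirna_id: str
    transcript_id: str
    start: int  # site on transcript, 0-based half-open
    end: int
    alignment: DuplexAlignment
    verdict: RuleVerdict


def classify_pair(mirna_base: str, site_base: str) -> str:
    """WC / GU / MM for one miRNA base against one (aligned) site base."""
    p = mirna_base + site_base
    if p in WC_PAIRS:
        return "WC"
    if p in GU_PAIRS:
        return "GU"
    return "MM"


def score_states(states: Sequence[str]) -> float:
    return sum(STATE_WEIGHT[s] for s in states)


def score_duplex(aln: DuplexAlignment | Sequence[str],
                 gu_in_runs: bool = True) -> RuleVerdict:
    """Evaluate rules 1-5 (and the total score) on a state vector.

    ``gu_in_runs`` controls whether G:U wobbles count as run members for
    the adjacency rules 2 and 3 (they always contribute 0.5 to scores).
    Alignments shorter than 12 positions cannot be judged and raise.
    """
    states = aln.states if isinstance(aln, DuplexAlignment) else tuple(aln)
    if len(states) < 12:
        raise ValueError("alignment shorter than 12 positions")
    score = score_states(states)

    in_run = [
        s != "WC" if gu_in_runs else s in ("MM", "GAP")
        for s in states
    ]
    longest = run = 0
    for flag in in_run:
        run = run + 1 if flag else 0
        longest = max(longest, run)

    rule1 = score <= 4.0
    rule2 = longest <= 2
    # positions 2-12, 1-based -> 0-based indices 1..11
    rule3 = not any(in_run[i] and in_run[i + 1] for i in range(1, 11))
    rule4 = states[9] == "WC" and states[10] == "WC"
    rule5 = score_states(states[:12]) <= 2.5
    return RuleVerdict(score, rule1, rule2, rule3, rule4, rule5, rule6=False)


def evaluate_energy(verdict: RuleVerdict, mirna: str, site: str,
                    cfg: TargetConfig | None = None) -> RuleVerdict:
    """Fill in the duplex/perfect MFE fields and rule 6.

    ``site`` is the target site 5'->3'.  The ratio is computed on energy
    magnitudes; a non-negative perfect-complement energy is an error.
    """
    cfg = cfg or TargetConfig()
    mfe_p = perfect_mfe(mirna)
    if mfe_p >= 0:
        raise ValueError("perfect complement forms no stable duplex")
    mfe_d = duplex_mfe(mirna, site)
    verdict.mfe_duplex = mfe_d
    verdict.mfe_perfect = mfe_p
    verdict.mfe_ratio = abs(mfe_d) / abs(mfe_p)
    verdict.rule6 = verdict.mfe_ratio >= cfg.mfe_ratio_min
    return verdict


def align_window(mirna: str, window: str,
                 allow_gap: bool = True) -> DuplexAlignment:
    """Best (lowest-score) alignment of a miRNA to one site window.

    The window is the transcript site 5'->3'; pairing is antiparallel, so
    miRNA position i faces window position L-1-i.  Windows of length
    len(mirna) are aligned ungapped; length +1 allows one bulged target
    nucleotide, length -1 one bulged miRNA nucleotide.
    """
    m = to_rna(mirna)
    w = to_rna(window)
    lm, lw = len(m), len(w)
    site_rev = w[::-1]  # 3'->5', index-aligned with the miRNA

    if lw == lm:
        states = tuple(classify_pair(m[i], site_rev[i]) for i in range(lm))
        return DuplexAlignment(m, site_rev, states)
    if not allow_gap or abs(lw - lm) != 1:
        raise ValueError("window length must be len(mirna) (+-1 with gaps)")

    best: tuple[float, tuple[str, ...]] | None = None
    if lw == lm + 1:
        # one bulged site nucleotide at (reversed) index g
        for g in range(lw):
            aligned = site_rev[:g] + site_rev[g + 1:]
            states = [classify_pair(m[i], aligned[i]) for i in range(lm)]
            states[min(g, lm - 1)] = "GAP"
            score = score_states(states)
            if best is None or score < best[0]:
                best = (score, tuple(states))
    else:
        # one bulged (unpaired) miRNA nucleotide at position g
        for g in range(lm):
            states = []
            for i in range(lm):
                if i == g:
                    states.append("GAP")
                else:
                    states.append(classify_pair(m[i], site_rev[i if i < g else i - 1]))
            score = score_states(states)
            if best is None or score < best[0]:
                best = (score, tuple(states))
    return DuplexAlignment(m, site_rev, best[1])


def scan_transcripts(mirna_id: str, mirna: str, transcripts: dict[str, str],
                     cfg: TargetConfig | None = None) -> list[TargetHit]:
    """All rule-passing sites of one miRNA over a transcript collection.

    Output order is deterministic: transcript file order, then site start.
    Overlapping calls on the same transcript are collapsed to the
    best-scoring (then leftmost, ungapped-first) one.
    """
    cfg = cfg or TargetConfig()
    m = to_rna(mirna)
    lm = len(m)
    hits: list[TargetHit] = []
    for t_id, t_seq in transcripts.items():
        t_rna = to_rna(t_seq)
        found: list[TargetHit] = []
        lengths = [lm] + ([lm + 1, lm - 1] if cfg.allow_gap else [])
        for start in range(len(t_rna) - lm + 2):
            for lw in lengths:
                if start + lw > len(t_rna) or lw < 12:
                    continue
                window = t_rna[start:start + lw]
                aln = align_window(m, window, allow_gap=cfg.allow_gap)
                verdict = score_duplex(aln, gu_in_runs=cfg.gu_in_runs)
                if not (verdict.rule1 and verdict.rule2 and verdict.rule3
                        and verdict.rule4 and verdict.rule5):
                    continue
                verdict = evaluate_energy(verdict, m, window, cfg)
                if verdict.all_pass:
                    found.append(TargetHit(mirna_id, t_id, start, start + lw,
                                           aln, verdict))
        hits.extend(_collapse_overlaps(found))
    return hits


def _collapse_overlaps(hits: list[TargetHit]) -> list[TargetHit]:
    chosen: list[TargetHit] = []
    for hit in sorted(hits, key=lambda h: (h.verdict.score, h.start, h.end - h.start)):
        if all(hit.end <= c.start or hit.start >= c.end for c in chosen):
            chosen.append(hit)
    return sorted(chosen, key=lambda h: h.start)


def format_duplex(aln: DuplexAlignment) -> str:
    """3-line ASCII duplex: miRNA 5'->3', pairing line, site 3'->5'."""
    bond = {"WC": "|", "GU": "o", "MM": " ", "GAP": "-"}
    mid = "".join(bond[s] for s in aln.states)
    return (f"miR  5' {aln.mirna} 3'\n"
            f"        {mid}\n"
            f"site 3' {aln.site} 5'")
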