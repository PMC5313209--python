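"""RNA secondary-structure thermodynamics on a reduced nearest-neighbour model.

Two energy problems are solved here:

* ``fold`` — intramolecular minimum-free-energy folding of a candidate
  precursor into a nested (pseudoknot-free) structure.  The model is a
  simplified Zuker recursion: Watson-Crick and G:U pairs, stacking
  energies for adjacent pairs, length-dependent hairpin / bulge /
  internal-loop penalties, no multibranch loops inside a closed pair
  (top-level helices are free to coexist).  Interior loops are capped in
  size, which is ample for miRNA hairpins.

* ``duplex_mfe`` / ``perfect_mfe`` — intermolecular hybridisation of a
  miRNA with a target site.  The duplex model is ungapped-register
  hybridisation: one duplex initiation penalty plus stacking energy over
  adjacent paired positions, minimised over all registers (and over the
  open chain, so the result is never positive).

Energies are Gibbs free energies at 37 °C in kcal/mol.  The parameter
tables are a compact stacking/loop set in the spirit of the Turner rules;
an external folding engine honouring the ``fold`` contract can be plugged
in via ``backend="vienna"`` (uses the RNAfold executable if present).
"""

from __future__ import annotations

import math
import shutil
import subprocess
from dataclasses import dataclass

from .seqio import to_rna

INF = float("inf")

#: Allowed base pairs (AU/GC/GU, both orientations).
PAIRS = {"AU", "UA", "CG", "GC", "GU", "UG"}

#: Stacking free energies, kcal/mol: STACK[p][q] is the energy of pair q
#: (at i+1, j-1) stacked inside closing pair p (at i, j), p written 5'->3'
#: as seq[i]seq[j].
STACK: dict[str, dict[str, float]] = {
    "AU": {"AU": -0.9, "CG": -2.2, "GC": -2.1, "GU": -0.6, "UA": -1.1, "UG": -1.4},
    "CG": {"AU": -2.1, "CG": -3.3, "GC": -2.4, "GU": -1.4, "UA": -2.1, "UG": -2.1},
    "GC": {"AU": -2.4, "CG": -3.4, "GC": -3.3, "GU": -1.5, "UA": -2.2, "UG": -2.5},
    "GU": {"AU": -1.3, "CG": -2.5, "GC": -2.1, "GU": -0.5, "UA": -1.4, "UG": 1.3},
    "UA": {"AU": -1.3, "CG": -2.4, "GC": -2.1, "GU": -1.0, "UA": -0.9, "UG": -1.3},
    "UG": {"AU": -1.0, "CG": -1.5, "GC": -1.4, "GU": 0.3, "UA": -0.6, "UG": -0.5},
}

_HAIRPIN = {3: 5.4, 4: 5.6, 5: 5.7, 6: 5.4, 7: 6.0, 8: 5.5, 9: 6.4}
_BULGE = {1: 3.8, 2: 2.8, 3: 3.2, 4: 3.6, 5: 4.0, 6: 4.4}
_INTERNAL = {2: 1.7, 3: 2.3, 4: 2.9, 5: 3.2, 6: 3.5}

#: Multibranch closing penalty (scoring only; the fold DP never emits one).
MULTILOOP_CLOSE = 3.4
MULTILOOP_BRANCH = 0.4

#: Intermolecular duplex initiation penalty, kcal/mol.
DUPLEX_INIT = 4.1

MIN_HAIRPIN_LOOP = 3
MAX_BULGE = 10
MAX_INTERNAL = 10
MAX_FOLD_LEN = 500


def _extrapolate(table: dict[int, float], n: int) -> float:
    nmax = max(table)
    if n in table:
        return table[n]
    # Jacobson-Stockmayer-style logarithmic extrapolation
    return table[nmax] + 1.08 * math.log(n / nmax)


def hairpin_energy(loop_size: int) -> float:
    if loop_size < MIN_HAIRPIN_LOOP:
        return INF
    return _extrapolate(_HAIRPIN, loop_size)


def bulge_energy(size: int) -> float:
    return _extrapolate(_BULGE, size)


def internal_energy(size: int) -> float:
    return _extrapolate(_INTERNAL, size)


def pair_type(a: str, b: str) -> str | None:
    p = a + b
    return p if p in PAIRS else None


def _validate_rna(sequence: str) -> str:
    seq = to_rna(sequence)
    bad = set(seq) - set("ACGU")
    if bad:
        raise ValueError(f"non-ACGU(T) characters in sequence: {sorted(bad)}")
    return seq


@dataclass(frozen=True)
class FoldResult:
    """A sequence, its MFE dot-bracket structure, and the MFE in kcal/mol."""

    sequence: str
    structure: str
    mfe: float

    @property
    def pairs(self) -> list[tuple[int, int]]:
        return pairs_from_dotbracket(self.structure)

    def pair_table(self) -> list[int]:
        """partner index per position, -1 if unpaired."""
        table = [-1] * len(self.structure)
        for i, j in self.pairs:
            table[i] = j
            table[j] = i
        return table


def pairs_from_dotbracket(structure: str) -> list[tuple[int, int]]:
    stack: list[int] = []
    pairs: list[tuple[int, int]] = []
    for i, c in enumerate(structure):
        if c == "(":
            stack.append(i)
        elif c == ")":
            if not stack:
                raise ValueError("unbalanced dot-bracket string")
            pairs.append((stack.pop(), i))
        elif c != ".":
            raise ValueError(f"invalid dot-bracket character {c!r}")
    if stack:
        raise ValueError("unbalanced dot-bracket string")
    return sorted(pairs)


def _interior_energy(seq: str, i: int, j: int, k: int, l: int) -> float:
    a, b = k - i - 1, j - l - 1
    if a == 0 and b == 0:
        return STACK[seq[i] + seq[j]][seq[k] + seq[l]]
    if a == 0 or b == 0:
        return bulge_energy(a + b)
    return internal_energy(a + b)


def fold(sequence: str, backend: str = "builtin") -> FoldResult:
    """Minimum-free-energy nested structure of an RNA (or DNA-alphabet) string.

    Ties prefer the less-paired alternative, so isolated energy-neutral
    pairs are never emitted.  ``backend="vienna"`` shells out to RNAfold.
    """
    seq = _validate_rna(sequence)
    if len(seq) > MAX_FOLD_LEN:
        raise ValueError(f"sequence longer than {MAX_FOLD_LEN} nt")
    if backend == "vienna":
        return _fold_vienna(seq)
    if backend != "builtin":
        raise ValueError(f"unknown folding backend {backend!r}")
    return _fold_builtin(seq)


def _fold_builtin(seq: str) -> FoldResult:
    n = len(seq)
    if n < MIN_HAIRPIN_LOOP + 2:
        return FoldResult(seq, "." * n, 0.0)

    can_pair = [[pair_type(seq[i], seq[j]) is not None for j in range(n)]
                for i in range(n)]
    V = [[INF] * n for _ in range(n)]
    # back-pointer per closed pair: ("hp",) or ("int", k, l)
    vbp: dict[tuple[int, int], tuple] = {}

    min_span = MIN_HAIRPIN_LOOP + 1
    for span in range(min_span, n):
        for i in range(0, n - span):
            j = i + span
            if not can_pair[i][j]:
                continue
            best = hairpin_energy(j - i - 1)
            bt: tuple = ("hp",)
            for a in range(0, MAX_BULGE + 1):
                k = i + 1 + a
                if k + MIN_HAIRPIN_LOOP + 1 > j - 1:
                    break
                row = V[k]
                for b in range(0, MAX_BULGE + 1):
                    l = j - 1 - b
                    if l < k + MIN_HAIRPIN_LOOP + 1:
                        break
                    if a > 0 and b > 0 and a + b > MAX_INTERNAL:
                        break
                    e_inner = row[l]
                    if e_inner == INF:
                        continue
                    e = e_inner + _interior_energy(seq, i, j, k, l)
                    if e < best:
                        best = e
                        bt = ("int", k, l)
            V[i][j] = best
            vbp[(i, j)] = bt

    # external level: any number of non-overlapping helices, no penalty
    W = [0.0] * (n + 1)  # W[j] = best energy of prefix seq[:j]
    wbp: list[tuple | None] = [None] * (n + 1)
    for j in range(1, n + 1):
        best = W[j - 1]
        bt = None
        for i in range(0, j - min_span):
            if V[i][j - 1] == INF:
                continue
            e = W[i] + V[i][j - 1]
            if e < best:
                best = e
                bt = (i, j - 1)
        W[j] = best
        wbp[j] = bt

    structure = ["."] * n
    stack: list[tuple[int, int]] = []
    j = n
    while j > 0:
        bt = wbp[j]
        if bt is None:
            j -= 1
        else:
            i, jj = bt
            stack.append((i, jj))
            j = i
    while stack:
        i, j = stack.pop()
        structure[i], structure[j] = "(", ")"
        move = vbp[(i, j)]
        if move[0] == "int":
            stack.append((move[1], move[2]))
    return FoldResult(seq, "".join(structure), round(W[n], 6))


def _fold_vienna(seq: str) -> FoldResult:
    exe = shutil.which("RNAfold")
    if exe is None:
        raise RuntimeError("RNAfold executable not found on PATH")
    out = subprocess.run(
        [exe, "--noPS"], input=seq + "\n", capture_output=True, text=True, check=True,
    ).stdout.splitlines()
    structure, _, energy = out[1].rpartition(" (")
    return FoldResult(seq, structure.strip(), float(energy.rstrip(")")))


def energy_of_structure(sequence: str, structure: str) -> float:
    """Free energy of a given dot-bracket structure, recomputed from scratch.

    Independent of the folding DP: the structure is decomposed into its
    loops (hairpin, stack/bulge/internal, multibranch) and each loop is
    scored from the parameter tables.  Used to check DP self-consistency.
    """
    seq = _validate_rna(sequence)
    if len(structure) != len(seq):
        raise ValueError("structure length != sequence length")
    pairs = pairs_from_dotbracket(structure)
    for i, j in pairs:
        if pair_type(seq[i], seq[j]) is None:
            raise ValueError(f"invalid pair {seq[i]}:{seq[j]} at ({i}, {j})")
    partner = {i: j for i, j in pairs} | {j: i for i, j in pairs}
    children: dict[tuple[int, int] | None, list[tuple[int, int]]] = {None: []}
    # assign each pair to its directly enclosing pair
    open_stack: list[tuple[int, int]] = []
    for pos in range(len(seq)):
        if pos in partner and partner[pos] > pos:
            pair = (pos, partner[pos])
            parent = open_stack[-1] if open_stack else None
            children.setdefault(parent, []).append(pair)
            children.setdefault(pair, [])
            open_stack.append(pair)
        elif pos in partner and partner[pos] < pos:
            open_stack.pop()

    def loop_energy(pair: tuple[int, int]) -> float:
        i, j = pair
        kids = children[pair]
        if not kids:
            return hairpin_energy(j - i - 1)
        if len(kids) == 1:
            k, l = kids[0]
            return _interior_energy(seq, i, j, k, l) + loop_energy((k, l))
        e = MULTILOOP_CLOSE + MULTILOOP_BRANCH * len(kids)
        return e + sum(loop_energy(kid) for kid in kids)

    return round(sum(loop_energy(p) for p in children[None]), 6)


# ---------------------------------------------------------------------------
# intermolecular hybridisation


def _register_energy(mirna: str, site_rev: str, r: int) -> float:
    """Stacking energy of one ungapped register (no initiation term).

    ``site_rev`` is the site read 3'->5' so that mirna[i] pairs
    site_rev[i + r].
    """
    lm, ls = len(mirna), len(site_rev)
    total = 0.0
    prev = None  # pair at previous miRNA position, or None
    for i in range(lm):
        j = i + r
        if 0 <= j < ls:
            p = pair_type(mirna[i], site_rev[j])
        else:
            p = None
        if p is not None and prev is not None:
            total += STACK[prev][p]
        prev = p
    return total


def duplex_mfe(mirna: str, site: str) -> float:
    """Hybridisation free energy of a miRNA with a target site, kcal/mol.

    ``site`` is the target 5'->3'; the duplex is antiparallel.  A linear
    dynamic program along every ungapped register accumulates stacking
    over adjacent pairs; the best register plus one duplex-initiation
    penalty is returned, clamped at 0 (the open chain).
    """
    if not mirna or not site:
        raise ValueError("empty sequence")
    m = _validate_rna(mirna)
    s_rev = _validate_rna(site)[::-1]
    best = 0.0
    for r in range(-(len(m) - 1), len(s_rev)):
        e = _register_energy(m, s_rev, r)
        if e < 0:
            e += DUPLEX_INIT
        if e < best:
            best = e
    return round(best, 6)


def perfect_mfe(mirna: str) -> float:
    """Energy of the miRNA bound to its exact Watson-Crick complement."""
    m = _validate_rna(mirna)
    complement = m.translate(str.maketrans("ACGU", "UGCA"))[::-1]
    return duplex_mfe(m, complement)
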