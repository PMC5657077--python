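"""RNA secondary structures, bounded-energy enumeration, and the move graph.

A secondary structure is a non-crossing set of base pairs ``(i, j)`` with
1-based coordinates, ``i < j``, a minimal hairpin of three unpaired bases
(``j - i >= 4``), and pairs drawn from the allowed complementarity alphabet
(Watson-Crick plus GU wobble by default).  The canonical serialization is
dot-bracket notation.

The elementary-move neighborhood connects two structures that differ by a
single base-pair insertion or deletion.  When lonely (unstacked) pairs are
excluded (``nolp``), the move set additionally contains double moves that
insert or delete a helix of exactly two pairs at once; a single move that
would create or leave a lonely pair is forbidden.  The double moves keep
lonely-pair-free structure spaces connected.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import Iterable, Iterator, Sequence

from .errors import InputError, ParseError, ValidityError

#: Default set of admissible base pairs (canonical plus GU wobble).
DEFAULT_PAIRS: frozenset[tuple[str, str]] = frozenset(
    [("A", "U"), ("U", "A"), ("G", "C"), ("C", "G"), ("G", "U"), ("U", "G")]
)

#: Minimal number of unpaired bases enclosed by a hairpin-closing pair.
MIN_HAIRPIN = 3

_DB_ORDER = str.maketrans("(.)", "012")


def dotbracket_key(db: str) -> str:
    """Deterministic tie-break key with the ordering ``'(' < '.' < ')'``."""
    return db.translate(_DB_ORDER)


def _check_sequence(seq: str) -> str:
    seq = seq.strip().upper().replace("T", "U")
    if not seq or any(c not in "ACGU" for c in seq):
        raise InputError(f"sequence must be non-empty over ACGU, got {seq!r}")
    return seq


@dataclass(frozen=True, order=False)
class Structure:
    """One RNA secondary structure in dot-bracket form.

    Attributes
    ----------
    dotbracket:
        String over ``{'.', '(', ')'}``; position ``k`` (1-based) is
        character ``dotbracket[k-1]``.
    pairs:
        Frozen set of 1-based pairs ``(i, j)`` with ``i < j``.
    """

    dotbracket: str
    pairs: frozenset[tuple[int, int]] = field(repr=False)

    def __len__(self) -> int:
        return len(self.dotbracket)

    @property
    def key(self) -> str:
        return dotbracket_key(self.dotbracket)

    @property
    def partner(self) -> dict[int, int]:
        """Map from each paired position to its partner (both directions)."""
        out: dict[int, int] = {}
        for i, j in self.pairs:
            out[i] = j
            out[j] = i
        return out

    def is_paired(self, k: int) -> bool:
        return self.dotbracket[k - 1] != "."


def pairs_to_dotbracket(length: int, pairs: Iterable[tuple[int, int]]) -> str:
    chars = ["."] * length
    for i, j in pairs:
        chars[i - 1] = "("
        chars[j - 1] = ")"
    return "".join(chars)


def structure_from_pairs(length: int, pairs: Iterable[tuple[int, int]]) -> Structure:
    ps = frozenset((int(i), int(j)) for i, j in pairs)
    return Structure(pairs_to_dotbracket(length, ps), ps)


def parse_dotbracket(s: str) -> Structure:
    """Parse a dot-bracket string into a :class:`Structure`.

    Raises
    ------
    ParseError
        On characters outside ``{'.', '(', ')'}`` or unbalanced brackets.
    ValidityError
        On hairpin loops shorter than three unpaired bases.
    """
    stack: list[int] = []
    pairs: set[tuple[int, int]] = set()
    for pos, c in enumerate(s, start=1):
        if c == "(":
            stack.append(pos)
        elif c == ")":
            if not stack:
                raise ParseError(f"unbalanced ')' at position {pos} in {s!r}")
            i = stack.pop()
            pairs.add((i, pos))
        elif c != ".":
            raise ParseError(f"illegal character {c!r} at position {pos} in {s!r}")
    if stack:
        raise ParseError(f"unbalanced '(' at position {stack[-1]} in {s!r}")
    st = Structure(s, frozenset(pairs))
    _check_hairpins(st)
    return st


def _check_hairpins(x: Structure) -> None:
    for i, j in x.pairs:
        if j - i < MIN_HAIRPIN + 1:
            raise ValidityError(
                f"pair ({i},{j}) encloses a hairpin of fewer than "
                f"{MIN_HAIRPIN} unpaired bases in {x.dotbracket!r}"
            )


def lonely_pairs(pairs: frozenset[tuple[int, int]]) -> set[tuple[int, int]]:
    """Pairs without a stacking neighbor on either side."""
    return {
        (i, j)
        for i, j in pairs
        if (i - 1, j + 1) not in pairs and (i + 1, j - 1) not in pairs
    }


def validate(
    x: Structure,
    seq: str | None = None,
    *,
    nolp: bool = False,
    allowed_pairs: frozenset[tuple[str, str]] = DEFAULT_PAIRS,
) -> None:
    """Check all structure invariants; raise :class:`ValidityError` if violated."""
    _check_hairpins(x)
    seen: set[int] = set()
    for i, j in x.pairs:
        if not (1 <= i < j <= len(x)):
            raise ValidityError(f"pair ({i},{j}) out of range for length {len(x)}")
        if i in seen or j in seen:
            raise ValidityError(f"position in more than one pair near ({i},{j})")
        seen.update((i, j))
    for (i, j), (k, l) in itertools.combinations(x.pairs, 2):
        if (i < k < j < l) or (k < i < l < j):
            raise ValidityError(f"crossing pairs ({i},{j}) and ({k},{l})")
    if seq is not None:
        seq = _check_sequence(seq)
        if len(seq) != len(x):
            raise InputError("sequence and structure lengths differ")
        for i, j in x.pairs:
            if (seq[i - 1], seq[j - 1]) not in allowed_pairs:
                raise ValidityError(
                    f"pair ({i},{j}) = {seq[i - 1]}{seq[j - 1]} not allowed"
                )
    if nolp and lonely_pairs(x.pairs):
        raise ValidityError(f"isolated base pair in {x.dotbracket!r}")


def _admissible(
    seq: str,
    pairs: frozenset[tuple[int, int]],
    i: int,
    j: int,
    partner: dict[int, int],
    allowed_pairs: frozenset[tuple[str, str]],
) -> bool:
    """Can pair (i, j) be added to ``pairs`` keeping validity (noLP aside)?"""
    if j - i < MIN_HAIRPIN + 1:
        return False
    if i in partner or j in partner:
        return False
    if (seq[i - 1], seq[j - 1]) not in allowed_pairs:
        return False
    for k, l in pairs:
        if (k < i < l < j) or (i < k < j < l):
            return False
    return True


def neighbors(
    x: Structure,
    seq: str,
    *,
    nolp: bool = False,
    allowed_pairs: frozenset[tuple[str, str]] = DEFAULT_PAIRS,
) -> list[Structure]:
    """All structures one elementary move away from ``x``.

    Without ``nolp`` these are exactly the single base-pair insertions and
    deletions.  With ``nolp``, single moves whose result contains a lonely
    pair are dropped and helix-of-two double moves are added (see module
    docstring); the relation stays symmetric in both dialects.
    """
    seq = _check_sequence(seq)
    L = len(seq)
    partner = x.partner
    out: list[Structure] = []

    for p in x.pairs:  # single deletions
        new = x.pairs - {p}
        if nolp and lonely_pairs(new):
            continue
        out.append(structure_from_pairs(L, new))

    candidates = [
        (i, j)
        for i in range(1, L + 1)
        for j in range(i + MIN_HAIRPIN + 1, L + 1)
        if _admissible(seq, x.pairs, i, j, partner, allowed_pairs)
    ]
    for i, j in candidates:  # single insertions
        new = x.pairs | {(i, j)}
        if nolp and lonely_pairs(new):
            continue
        out.append(structure_from_pairs(L, new))

    if nolp:
        cand = set(candidates)
        for i, j in candidates:  # double insertions of a 2-stack
            inner = (i + 1, j - 1)
            if inner not in cand:
                continue
            # only when neither pair could have been inserted alone
            if not lonely_pairs(x.pairs | {(i, j)}):
                continue
            if not lonely_pairs(x.pairs | {inner}):
                continue
            new = x.pairs | {(i, j), inner}
            if not lonely_pairs(new):
                out.append(structure_from_pairs(L, new))
        for i, j in x.pairs:  # double deletions of an isolated 2-stack
            inner = (i + 1, j - 1)
            if inner not in x.pairs:
                continue
            if (i - 1, j + 1) in x.pairs or (i + 2, j - 2) in x.pairs:
                continue
            new = x.pairs - {(i, j), inner}
            if not lonely_pairs(new):
                out.append(structure_from_pairs(L, new))

    out = [y for y in out if y.pairs != x.pairs]
    out.sort(key=lambda y: y.key)
    return out


def _enumerate_pairsets(
    seq: str,
    allowed_pairs: frozenset[tuple[str, str]],
    max_count: int,
) -> list[frozenset[tuple[int, int]]]:
    """Enumerate every non-crossing admissible pair set by interval recursion."""
    memo: dict[tuple[int, int], list[frozenset[tuple[int, int]]]] = {}

    def rec(i: int, j: int) -> list[frozenset[tuple[int, int]]]:
        if i >= j:
            return [frozenset()]
        key = (i, j)
        if key in memo:
            return memo[key]
        result = list(rec(i + 1, j))  # position i unpaired
        for k in range(i + MIN_HAIRPIN + 1, j + 1):
            if (seq[i - 1], seq[k - 1]) not in allowed_pairs:
                continue
            for left in rec(i + 1, k - 1):
                for right in rec(k + 1, j):
                    result.append(left | right | {(i, k)})
                    if len(result) > max_count:
                        raise InputError(
                            f"structure space exceeds {max_count} states; "
                            "tighten the sequence or use an energy band"
                        )
        memo[key] = result
        return result

    return rec(1, len(seq))


def enumerate_structures(
    seq: str,
    energy_model,
    band: float | None = None,
    *,
    nolp: bool = False,
    allowed_pairs: frozenset[tuple[str, str]] = DEFAULT_PAIRS,
    max_length: int = 40,
    max_count: int = 2_000_000,
) -> list[tuple[Structure, float]]:
    """Exhaustively enumerate the structure space within an energy band.

    Returns exactly the structures with ``E(x) <= E_mfe + band`` (all
    structures when ``band`` is ``None``), each with its energy, sorted by
    energy ascending with lexicographic dot-bracket tie-break.

    Parameters
    ----------
    seq:
        RNA sequence (ACGU; T is read as U).
    energy_model:
        Object with an ``energy(structure, seq)`` method (kcal/mol).
    band:
        Energy band above the minimum free energy, kcal/mol, ``>= 0``.
    nolp:
        Exclude structures containing isolated base pairs.
    """
    seq = _check_sequence(seq)
    if len(seq) > max_length:
        raise InputError(
            f"built-in exhaustive enumeration is limited to {max_length} nt "
            f"(got {len(seq)}); use an external structure list instead"
        )
    if band is not None and band < 0:
        raise InputError("energy band must be non-negative")

    scored: list[tuple[Structure, float]] = []
    for ps in _enumerate_pairsets(seq, allowed_pairs, max_count):
        if nolp and lonely_pairs(ps):
            continue
        st = structure_from_pairs(len(seq), ps)
        scored.append((st, float(energy_model.energy(st, seq))))

    e_mfe = min(e for _, e in scored)
    if band is not None:
        scored = [(s, e) for s, e in scored if e <= e_mfe + band + 1e-9]
    scored.sort(key=lambda se: (round(se[1], 9), se[0].key))
    return scored


# ---------------------------------------------------------------------------
# sequence and suboptimal-structure file I/O
# ---------------------------------------------------------------------------


def read_sequence(source: str) -> str:
    """Read an RNA sequence from a FASTA file path or a raw string.

    A path to an existing file is parsed as single-record FASTA; any other
    string is taken as the sequence itself.
    """
    import os

    if os.path.exists(source):
        with open(source) as fh:
            lines = [ln.strip() for ln in fh if ln.strip()]
        if lines and lines[0].startswith(">"):
            body = []
            for ln in lines[1:]:
                if ln.startswith(">"):
                    raise InputError("expected a single FASTA record")
                body.append(ln)
            return _check_sequence("".join(body))
        return _check_sequence("".join(lines))
    return _check_sequence(source)


def write_subopt(path: str, seq: str, entries: Sequence[tuple[Structure, float]]) -> None:
    """Write the suboptimal-structure dialect: header line with the sequence,
    then one ``DOTBRACKET ENERGY`` line per structure (two decimals)."""
    with open(path, "w") as fh:
        fh.write(f"{seq}\n")
        for st, e in entries:
            fh.write(f"{st.dotbracket} {e:.2f}\n")


def read_subopt(path: str) -> tuple[str, list[tuple[Structure, float]]]:
    """Read the suboptimal-structure dialect written by :func:`write_subopt`.

    The header's first whitespace-separated field is the sequence; optional
    further header fields are ignored.  Round-trips bit-exactly with
    :func:`write_subopt`.
    """
    with open(path) as fh:
        lines = [ln.rstrip("\n") for ln in fh if ln.strip()]
    if not lines:
        raise ParseError(f"empty suboptimal-structure file {path!r}")
    seq = _check_sequence(lines[0].split()[0])
    entries: list[tuple[Structure, float]] = []
    for ln in lines[1:]:
        fields = ln.split()
        if len(fields) < 2:
            raise ParseError(f"malformed structure line {ln!r}")
        st = parse_dotbracket(fields[0])
        if len(st) != len(seq):
            raise ParseError(f"structure length differs from sequence in {ln!r}")
        entries.append((st, float(fields[1])))
    return seq, entries


def iter_moves(entries: Iterable[Structure]) -> Iterator[tuple[Structure, Structure]]:
    """Yield each unordered neighbor pair among ``entries`` once (pairs whose
    pair sets differ by exactly one base pair)."""
    items = list(entries)
    for a, b in itertools.combinations(items, 2):
        if len(a.pairs ^ b.pairs) == 1:
            yield a, b
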