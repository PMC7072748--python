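"""Conservation of splice-site combinations across homologous transcripts.

Each transcript's ordered intron combinations are encoded as a short symbol
string (one amino-acid-like letter per intron), homologous strings are
globally aligned, and the homolog symbols aligned to a query's non-canonical
positions are tallied as identical / other non-canonical / canonical GT-AG.
Homology pairs are supplied externally; this module never searches for them.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .annotation import CANONICAL, IntronRecord, classify_combination

#: symbols available for frequent combinations; GT-AG is pinned to 'G'
CANONICAL_SYMBOL = "G"
RARE_SYMBOL = "X"
_FREE_SYMBOLS = "ACDEFHIKLMNPQRSTVW"  # 18 letters, 'G' and 'X' reserved
GAP = "-"


@dataclass
class CombinationString:
    """One transcript's intron combinations as a symbol string."""

    transcript_id: str
    species_id: str
    symbols: str
    codebook: dict[str, str]

    def combination_at(self, pos: int) -> str | None:
        """Combination behind position ``pos`` (0-based), None for rare."""
        inverse = {v: k for k, v in self.codebook.items() if v != RARE_SYMBOL}
        return inverse.get(self.symbols[pos])


@dataclass
class ConservationCount:
    """Fate of one query non-canonical position across homologs."""

    query_transcript: str
    query_position: int  # 0-based intron index in the query
    query_combination: str
    n_same: int = 0
    n_other_nc: int = 0
    n_canonical: int = 0
    n_gap: int = 0  # aligned only to gaps; excluded from the partition

    @property
    def n_aligned(self) -> int:
        return self.n_same + self.n_other_nc + self.n_canonical


def build_codebook(global_counts: Mapping[str, int]) -> dict[str, str]:
    """Deterministic combination -> symbol map.

    GT-AG always maps to the same symbol; the next 18 globally most frequent
    combinations (descending count, ties lexicographic) get fixed distinct
    letters; everything else shares the rare symbol.
    """
    codebook = {CANONICAL: CANONICAL_SYMBOL}
    ranked = sorted(
        (c for c in global_counts if c != CANONICAL),
        key=lambda c: (-global_counts[c], c),
    )
    for combo, symbol in zip(ranked, _FREE_SYMBOLS):
        codebook[combo] = symbol
    for combo in ranked[len(_FREE_SYMBOLS):]:
        codebook[combo] = RARE_SYMBOL
    return codebook


def encode(
    introns: Sequence[IntronRecord],
    codebook: Mapping[str, str],
    species_id: str = "species",
) -> CombinationString:
    """Encode one transcript's ordered introns with a shared codebook."""
    transcript_id = introns[0].transcript_id if introns else ""
    symbols = "".join(codebook.get(i.combination, RARE_SYMBOL) for i in introns)
    return CombinationString(
        transcript_id=transcript_id,
        species_id=species_id,
        symbols=symbols,
        codebook=dict(codebook),
    )


def align_strings(
    a: CombinationString | str,
    b: CombinationString | str,
    match: int = 1,
    mismatch: int = 0,
    gap: int = -1,
) -> tuple[str, str, int]:
    """Global (Needleman-Wunsch) alignment of two symbol strings.

    Returns (aligned_a, aligned_b, score).  Traceback ties are broken
    deterministically: diagonal (match/mismatch) beats a gap in ``a``
    (consuming ``b``), which beats a gap in ``b``.
    """
    sa = a.symbols if isinstance(a, CombinationString) else a
    sb = b.symbols if isinstance(b, CombinationString) else b
    n, m = len(sa), len(sb)
    score = [[0] * (m + 1) for _ in range(n + 1)]
    for i in range(1, n + 1):
        score[i][0] = i * gap
    for j in range(1, m + 1):
        score[0][j] = j * gap
    for i in range(1, n + 1):
        row, prev = score[i], score[i - 1]
        ca = sa[i - 1]
        for j in range(1, m + 1):
            diag = prev[j - 1] + (match if ca == sb[j - 1] else mismatch)
            row[j] = max(diag, row[j - 1] + gap, prev[j] + gap)
    # traceback with fixed preference: diagonal > gap-in-a > gap-in-b
    out_a, out_b = [], []
    i, j = n, m
    while i > 0 or j > 0:
        if i > 0 and j > 0 and score[i][j] == score[i - 1][j - 1] + (
            match if sa[i - 1] == sb[j - 1] else mismatch
        ):
            out_a.append(sa[i - 1])
            out_b.append(sb[j - 1])
            i, j = i - 1, j - 1
        elif j > 0 and score[i][j] == score[i][j - 1] + gap:
            out_a.append(GAP)
            out_b.append(sb[j - 1])
            j -= 1
        else:
            out_a.append(sa[i - 1])
            out_b.append(GAP)
            i -= 1
    return "".join(reversed(out_a)), "".join(reversed(out_b)), score[n][m]


def conservation_counts(
    query: CombinationString,
    homologs: Iterable[CombinationString],
) -> list[ConservationCount]:
    """Tally homolog symbols aligned to each non-canonical query position.

    For every query intron whose combination is non-canonical, each homolog
    contributes one of: the identical combination, a different non-canonical
    combination, or canonical GT-AG; homologs placing a gap there are counted
    separately and excluded from the three-way partition.
    """
    inverse = {v: k for k, v in query.codebook.items() if v != RARE_SYMBOL}
    results: dict[int, ConservationCount] = {}
    for pos, symbol in enumerate(query.symbols):
        if symbol == CANONICAL_SYMBOL:
            continue
        combo = inverse.get(symbol, "rare")
        results[pos] = ConservationCount(
            query_transcript=query.transcript_id,
            query_position=pos,
            query_combination=combo,
        )
    if not results:
        return []
    for homolog in homologs:
        aligned_q, aligned_h, _ = align_strings(query, homolog)
        qpos = -1
        for qa, ha in zip(aligned_q, aligned_h):
            if qa != GAP:
                qpos += 1
            if qa == GAP or qpos not in results:
                continue
            count = results[qpos]
            if ha == GAP:
                count.n_gap += 1
            elif ha == qa:
                count.n_same += 1
            elif ha == CANONICAL_SYMBOL:
                count.n_canonical += 1
            else:
                count.n_other_nc += 1
    return [results[pos] for pos in sorted(results)]


def counts_table(counts: Iterable[ConservationCount]) -> pd.DataFrame:
    rows = [
        {
            "query_transcript": c.query_transcript,
            "query_position": c.query_position,
            "query_combination": c.query_combination,
            "n_same": c.n_same,
            "n_other_noncanonical": c.n_other_nc,
            "n_canonical": c.n_canonical,
            "n_gap": c.n_gap,
        }
        for c in counts
    ]
    return pd.DataFrame(rows)


def read_homolog_pairs(path) -> pd.DataFrame:
    """Read a homolog pair TSV: query-transcript, species, homolog-transcript."""
    return pd.read_csv(
        path, sep="\t", comment="#", header=None,
        names=["query_transcript", "species", "homolog_transcript"],
    )
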