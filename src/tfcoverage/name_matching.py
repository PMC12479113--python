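"""Cell-line name matching across resources.

Expression atlases and ChIP-seq databases spell cell-line names differently
("K-562" vs "K562", "Hep G2" vs "HepG2").  Names are matched by Jaro-Winkler
similarity computed on normalized strings, with an additional digit
consistency check on the raw strings (so that K-562 can never match K-563 no
matter how similar the letters are), followed by greedy one-to-one
assignment.
"""

from __future__ import annotations

import re
from dataclasses import dataclass

import pandas as pd

_NORMALIZE_RE = re.compile(r"[\s\-_.]+")


@dataclass(frozen=True)
class NameMatch:
    source_name: str
    target_name: str
    similarity: float
    digit_ok: bool
    accepted: bool


def normalize_name(s: str) -> str:
    """Case-fold and strip whitespace/hyphen/underscore/period runs."""
    return _NORMALIZE_RE.sub("", s.strip().casefold())


def jaro(a: str, b: str) -> float:
    """Jaro similarity: matches within window floor(max(|a|,|b|)/2)-1,
    transpositions counted over the matched subsequences."""
    if a == b:
        return 1.0
    la, lb = len(a), len(b)
    if la == 0 or lb == 0:
        return 0.0
    window = max(la, lb) // 2 - 1
    a_matched = [False] * la
    b_matched = [False] * lb
    m = 0
    for i, ca in enumerate(a):
        lo = max(0, i - window)
        hi = min(lb, i + window + 1)
        for j in range(lo, hi):
            if not b_matched[j] and b[j] == ca:
                a_matched[i] = b_matched[j] = True
                m += 1
                break
    if m == 0:
        return 0.0
    bs = [b[j] for j in range(lb) if b_matched[j]]
    t = sum(1 for ca, cb in zip((a[i] for i in range(la) if a_matched[i]), bs)
            if ca != cb) / 2.0
    return (m / la + m / lb + (m - t) / m) / 3.0


def jaro_winkler(a: str, b: str, prefix_weight: float = 0.1,
                 max_prefix: int = 4) -> float:
    """Jaro-Winkler similarity: Jaro boosted by a shared prefix of length
    up to ``max_prefix`` with scaling ``prefix_weight`` (standard p = 0.1)."""
    sim = jaro(a, b)
    ell = 0
    for ca, cb in zip(a[:max_prefix], b[:max_prefix]):
        if ca != cb:
            break
        ell += 1
    return sim + ell * prefix_weight * (1.0 - sim)


def digit_consistent(a: str, b: str) -> bool:
    """True iff the multisets of digit characters in a and b are equal."""
    return sorted(c for c in a if c.isdigit()) == \
        sorted(c for c in b if c.isdigit())


def match_cell_lines(list_a, list_b, threshold: float = 0.9) -> pd.DataFrame:
    """Greedy one-to-one matching of two name lists.

    All candidate pairs are scored by Jaro-Winkler similarity on normalized
    names and ranked (descending similarity, ties by lexicographic pair); a
    pair is accepted iff its similarity reaches ``threshold``, its raw names
    are digit-consistent, and neither side is already matched.

    Returns the full candidate log (columns source_name, target_name,
    similarity, digit_ok, accepted), suitable for audit.
    """
    if not 0.0 <= threshold <= 1.0:
        raise ValueError("threshold must be in [0, 1]")
    rows = []
    for a in list_a:
        na = normalize_name(a)
        for b in list_b:
            sim = jaro_winkler(na, normalize_name(b))
            rows.append((a, b, sim, digit_consistent(a, b)))
    cand = pd.DataFrame(rows, columns=["source_name", "target_name",
                                       "similarity", "digit_ok"])
    cand = cand.sort_values(["similarity", "source_name", "target_name"],
                            ascending=[False, True, True],
                            kind="mergesort").reset_index(drop=True)
    used_a: set[str] = set()
    used_b: set[str] = set()
    accepted = []
    for r in cand.itertuples(index=False):
        ok = (r.similarity >= threshold and r.digit_ok
              and r.source_name not in used_a and r.target_name not in used_b)
        if ok:
            used_a.add(r.source_name)
            used_b.add(r.target_name)
        accepted.append(ok)
    cand["accepted"] = accepted
    return cand


def accepted_pairs(matches: pd.DataFrame) -> dict[str, str]:
    """Accepted source -> target mapping from a match_cell_lines log."""
    acc = matches[matches["accepted"]]
    return dict(zip(acc["source_name"], acc["target_name"]))
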