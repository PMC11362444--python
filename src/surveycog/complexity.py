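"""Item-complexity coding: ten binary indicators and a 0-10 composite.

Complexity here means the information load of a survey question.  Ten binary
characteristics are coded per item:

1.  WC  — word count at or above a threshold (default 10 words)
2.  DC  — two or more words absent from a familiar-word (Dale-Chall-style) list
3.  UTT — unfamiliar technical terms        (precomputed flag, e.g. from QUAID)
4.  VRT — vague/imprecise relative terms    (precomputed flag)
5.  VNP — vague/ambiguous noun phrases      (precomputed flag)
6.  CON — contains any conjunction
7.  NEG — contains any negation
8.  DIS — contains any discrepancy word (should, would, could, ...)
9.  TEN — contains any tentativeness word (maybe, perhaps, ...)
10. EXC — contains any differentiation/exclusion word (but, else, ...)

The composite is the sum of the ten binaries (0-10), and a five-level bin is
derived from the 0-1 / 2-3 / 4-5 / 6-7 / 8-9 partition (composites above 9
fall in the top bin).  Indicators 3-5 are ingested as precomputed input; the
lexical indicators use word lists shipped with the package, which are open
approximations (see the ``lexicons`` data directory) and can be replaced by
the user.
"""

from __future__ import annotations

import re
import warnings
from dataclasses import dataclass
from importlib import resources
from pathlib import Path

import pandas as pd

__all__ = [
    "Lexicons",
    "load_lexicons",
    "tokenize",
    "word_count_indicator",
    "dale_chall_indicator",
    "liwc_style_indicators",
    "load_precomputed_flags",
    "composite_and_bins",
    "code_items",
    "INDICATOR_COLUMNS",
    "LEXICAL_CATEGORIES",
]

INDICATOR_COLUMNS = ["WC", "DC", "UTT", "VRT", "VNP", "CON", "NEG", "DIS", "TEN", "EXC"]
LEXICAL_CATEGORIES = {
    "CON": "conjunctions_synthetic.txt",
    "NEG": "negations_synthetic.txt",
    "DIS": "discrepancy_synthetic.txt",
    "TEN": "tentative_synthetic.txt",
    "EXC": "differentiation_synthetic.txt",
}
_TOKEN_RE = re.compile(r"[a-z0-9]+(?:['\-][a-z0-9]+)*")


@dataclass(frozen=True)
class Lexicons:
    """Word lists for the lexical indicators.

    ``dale_chall`` is the familiar-word set; ``categories`` maps each of
    CON/NEG/DIS/TEN/EXC to a (word set, stem tuple) pair.  Stems match any
    token that starts with them.
    """

    dale_chall: frozenset
    categories: dict

    def category_match(self, token: str, cat: str) -> bool:
        words, stems = self.categories[cat]
        return token in words or any(token.startswith(s) for s in stems)


def _read_wordlist(path) -> tuple[frozenset, tuple]:
    words, stems = set(), set()
    for line in Path(path).read_text().splitlines():
        w = line.strip().lower()
        if not w or w.startswith("#"):
            continue
        if w.endswith("*"):
            stems.add(w[:-1])
        else:
            words.add(w)
    return frozenset(words), tuple(sorted(stems))


def load_lexicons(directory: str | Path | None = None) -> Lexicons:
    """Load the shipped lexicons (or replacements from ``directory``, which
    must contain files with the same names)."""
    if directory is None:
        directory = resources.files(__package__) / "lexicons"
    directory = Path(str(directory))
    dc_words, dc_stems = _read_wordlist(directory / "dale_chall_synthetic.txt")
    if dc_stems:
        raise ValueError("the familiar-word list must not contain stems")
    cats = {}
    for cat, fname in LEXICAL_CATEGORIES.items():
        cats[cat] = _read_wordlist(directory / fname)
    return Lexicons(dale_chall=dc_words, categories=cats)


def tokenize(text: str) -> list[str]:
    """Lowercase tokens: maximal runs of letters/digits with intra-word
    apostrophes and hyphens kept (hyphenated forms count as one token)."""
    return _TOKEN_RE.findall(str(text).lower())


def word_count_indicator(text: str, threshold: int = 10) -> int:
    """1 if the item has at least ``threshold`` words ('longer' item)."""
    tokens = tokenize(text)
    if not tokens:
        raise ValueError("cannot code an empty item text")
    return int(len(tokens) >= threshold)


def _off_list(token: str, lexicons: Lexicons) -> bool:
    if token in lexicons.dale_chall:
        return False
    # possessives of familiar words count as familiar
    if token.endswith("'s") and token[:-2] in lexicons.dale_chall:
        return False
    return True


def dale_chall_indicator(text: str, lexicons: Lexicons, threshold: int = 2) -> int:
    """1 if at least ``threshold`` words fall outside the familiar-word list
    (greater verbal ability required)."""
    tokens = tokenize(text)
    if not tokens:
        raise ValueError("cannot code an empty item text")
    n_off = sum(_off_list(t, lexicons) for t in tokens)
    return int(n_off >= threshold)


def liwc_style_indicators(text: str, lexicons: Lexicons) -> dict:
    """Contained-any binaries for CON, NEG, DIS, TEN, EXC."""
    tokens = tokenize(text)
    out = {}
    for cat in ("CON", "NEG", "DIS", "TEN", "EXC"):
        out[cat] = int(any(lexicons.category_match(t, cat) for t in tokens))
    return out


def load_precomputed_flags(flags: pd.DataFrame, item_ids=None) -> pd.DataFrame:
    """Validate a precomputed-flag table (item_id, UTT, VRT, VNP; 0/1 only)."""
    required = ["item_id", "UTT", "VRT", "VNP"]
    missing = [c for c in required if c not in flags.columns]
    if missing:
        raise ValueError(f"flag table missing columns: {missing}")
    flags = flags.copy()
    flags["item_id"] = flags["item_id"].astype(str)
    bad = []
    for col in ("UTT", "VRT", "VNP"):
        off = flags.loc[~flags[col].isin([0, 1]), "item_id"].tolist()
        bad += [(col, i) for i in off]
    if bad:
        raise ValueError(f"non-binary flag values for (column, item): {bad}")
    flags = flags.set_index("item_id")[["UTT", "VRT", "VNP"]].astype(int)
    if item_ids is not None:
        item_ids = [str(i) for i in item_ids]
        absent = sorted(set(item_ids) - set(flags.index))
        if absent:
            raise ValueError(f"flag table missing items: {absent}")
        flags = flags.loc[item_ids]
    return flags


def composite_and_bins(indicators: pd.DataFrame) -> pd.DataFrame:
    """Attach composite (sum of the ten binaries) and the five-level bin."""
    missing = [c for c in INDICATOR_COLUMNS if c not in indicators.columns]
    if missing:
        raise ValueError(f"missing indicator columns: {missing}")
    out = indicators.copy()
    out["composite"] = out[INDICATOR_COLUMNS].sum(axis=1).astype(int)
    out["bin"] = (out["composite"] // 2 + 1).clip(upper=5).astype(int)
    return out


def code_items(
    items: pd.DataFrame,
    quaid_flags: pd.DataFrame | None = None,
    lexicons: Lexicons | None = None,
    wc_threshold: int = 10,
    dc_threshold: int = 2,
    thresholds_from_median: bool = False,
    strict: bool = True,
) -> pd.DataFrame:
    """Code all ten complexity indicators for a table of items.

    Parameters
    ----------
    items : DataFrame with columns ``item_id`` and ``item_text``
    quaid_flags : optional precomputed UTT/VRT/VNP table.  When absent and
        ``strict`` is False, the three flags default to 0 with a warning;
        when absent and ``strict`` is True, an error is raised.
    thresholds_from_median : recompute the WC and DC split points as medians
        of the supplied item set instead of the printed defaults (10 words,
        2 off-list words).

    Returns a DataFrame indexed by item_id with the ten binaries, the 0-10
    composite and the five-level bin.
    """
    if lexicons is None:
        lexicons = load_lexicons()
    item_ids = items["item_id"].astype(str).tolist()
    texts = items["item_text"].tolist()

    counts = [len(tokenize(t)) for t in texts]
    off = [sum(_off_list(tok, lexicons) for tok in tokenize(t)) for t in texts]
    if thresholds_from_median:
        wc_threshold = int(pd.Series(counts).median())
        dc_threshold = max(int(pd.Series(off).median()), 1)

    rows = []
    for text, n_words, n_off in zip(texts, counts, off):
        if n_words == 0:
            raise ValueError("cannot code an empty item text")
        row = {"WC": int(n_words >= wc_threshold), "DC": int(n_off >= dc_threshold)}
        row.update(liwc_style_indicators(text, lexicons))
        rows.append(row)
    profile = pd.DataFrame(rows, index=pd.Index(item_ids, name="item_id"))

    if quaid_flags is not None:
        flags = load_precomputed_flags(quaid_flags, item_ids)
        profile[["UTT", "VRT", "VNP"]] = flags
    elif strict:
        raise ValueError(
            "precomputed UTT/VRT/VNP flags are required (pass strict=False to default them to 0)"
        )
    else:
        warnings.warn("no precomputed UTT/VRT/VNP flags supplied; defaulting to 0")
        profile[["UTT", "VRT", "VNP"]] = 0

    profile = profile[INDICATOR_COLUMNS]
    return composite_and_bins(profile)
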