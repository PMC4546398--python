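"""Tag extraction and library cleaning.

SuperSAGE counts 26-bp transcript tags cut at the 3'-most NlaIII anchor site
(CATG) by the type-III enzyme EcoP15I.  This module extracts canonical tags
from transcripts, parses raw ditag reads into per-library tag multisets, and
applies the cleaning filters used on SAGE libraries before any statistics:
removal of incomplete/twin ditags, poly-A artifact tags, and singletons.
"""

from __future__ import annotations

import io
from collections import Counter
from dataclasses import dataclass, replace
from pathlib import Path
from typing import Iterable, Mapping

import pandas as pd

TAG_LENGTH = 26
ANCHOR = "CATG"

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


class InputError(ValueError):
    """Malformed sequence or table input."""


class ConfigError(ValueError):
    """Invalid parameter or configuration value."""


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass(frozen=True)
class TagCountTable:
    """Per-tag raw counts in the two libraries plus the library totals.

    ``counts`` has columns ``tag``, ``count_ctl``, ``count_inf`` with unique
    tags.  ``n_ctl`` and ``n_inf`` are the library sizes N1 (control,
    non-infected) and N2 (infected); after filtering they exceed the column
    sums, before filtering they equal them.
    """

    counts: pd.DataFrame
    n_ctl: int
    n_inf: int

    def __post_init__(self) -> None:
        missing = {"tag", "count_ctl", "count_inf"} - set(self.counts.columns)
        if missing:
            raise InputError(f"count table lacks columns: {sorted(missing)}")
        if self.n_ctl < 0 or self.n_inf < 0:
            raise InputError("library totals must be non-negative")
        if self.counts["tag"].duplicated().any():
            raise InputError("tags must be unique")

    def __len__(self) -> int:
        return len(self.counts)

    @property
    def tags(self) -> pd.Series:
        return self.counts["tag"]

    def to_tsv(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            fh.write(f"# n_ctl={self.n_ctl}\n# n_inf={self.n_inf}\n")
            self.counts.to_csv(fh, sep="\t", index=False)

    @classmethod
    def from_tsv(cls, path: str | Path) -> "TagCountTable":
        meta: dict[str, int] = {}
        with open(path) as fh:
            pos = fh.tell()
            line = fh.readline()
            while line.startswith("#"):
                key, _, val = line[1:].strip().partition("=")
                meta[key.strip()] = int(val)
                pos = fh.tell()
                line = fh.readline()
            fh.seek(pos)
            df = pd.read_csv(fh, sep="\t", dtype={"tag": str})
        df["count_ctl"] = df["count_ctl"].astype(int)
        df["count_inf"] = df["count_inf"].astype(int)
        n_ctl = meta.get("n_ctl", int(df["count_ctl"].sum()))
        n_inf = meta.get("n_inf", int(df["count_inf"].sum()))
        return cls(df, n_ctl, n_inf)


def _validate_nucleotides(seq: str, alphabet: str = "ACGT") -> None:
    for i, ch in enumerate(seq):
        if ch not in alphabet:
            raise InputError(f"non-{alphabet} character {ch!r} at position {i}")


def extract_canonical_tag(
    transcript: str, anchor: str = ANCHOR, length: int = TAG_LENGTH
) -> str | None:
    """Return the canonical tag of a transcript, or None.

    The canonical tag is the ``length``-mer starting at the 3'-most anchor
    occurrence that still has ``length - len(anchor)`` bases downstream of
    the anchor, mirroring EcoP15I cutting at the last NlaIII site.
    """
    transcript = transcript.upper()
    _validate_nucleotides(transcript)
    limit = len(transcript) - length
    pos = transcript.rfind(anchor, 0, limit + len(anchor))
    if pos < 0 or pos > limit:
        return None
    return transcript[pos : pos + length]


def parse_ditags(
    reads: Iterable[str],
    linkers: Mapping[str, str],
    length: int = TAG_LENGTH,
) -> tuple[dict[str, Counter], dict[str, int]]:
    """Split raw ditag reads into per-library tag multisets.

    A read is accepted when it starts with exactly one library linker and
    carries at least ``2 * length`` bases after it; the first two tag-length
    windows form the ditag.  Rejection reasons: ``no_linker`` (no linker
    prefix), ``incomplete`` (too short after linker removal), ``twin_ditag``
    (the two tags are identical or exact reverse complements — duplicated
    ligation products).  Accepted + rejected counts always equal the number
    of input reads.
    """
    if len(set(linkers.values())) != len(linkers):
        raise ConfigError("linker sequences must be distinct")
    tag_sets: dict[str, Counter] = {lib: Counter() for lib in linkers}
    rejections: dict[str, int] = {"no_linker": 0, "incomplete": 0, "twin_ditag": 0}
    for read in reads:
        read = read.upper()
        lib = next((l for l, s in linkers.items() if read.startswith(s)), None)
        if lib is None:
            rejections["no_linker"] += 1
            continue
        body = read[len(linkers[lib]) :]
        if len(body) < 2 * length:
            rejections["incomplete"] += 1
            continue
        a, b = body[:length], body[length : 2 * length]
        if a == b or a == reverse_complement(b):
            rejections["twin_ditag"] += 1
            continue
        tag_sets[lib][a] += 1
        tag_sets[lib][b] += 1
    return tag_sets, rejections


def _is_polya(tag: str, max_a_fraction: float, max_terminal_a_run: int) -> bool:
    if tag.count("A") / len(tag) > max_a_fraction:
        return True
    run = len(tag) - len(tag.rstrip("A"))
    return run >= max_terminal_a_run


def filter_polya(
    table: TagCountTable,
    max_a_fraction: float = 0.8,
    max_terminal_a_run: int = 15,
) -> tuple[TagCountTable, int]:
    """Drop adenosine-rich artifact tags (oligo-dT priming / poly-A tails).

    A tag is removed when its A fraction exceeds ``max_a_fraction`` or its
    3'-terminal run of A is at least ``max_terminal_a_run`` bases.  Row order
    of retained tags is preserved.  Returns the filtered table and the
    number of removed tags.
    """
    if not 0 < max_a_fraction <= 1:
        raise ConfigError("max_a_fraction must be in (0, 1]")
    if max_terminal_a_run < 1:
        raise ConfigError("max_terminal_a_run must be >= 1")
    keep = ~table.counts["tag"].map(
        lambda t: _is_polya(t, max_a_fraction, max_terminal_a_run)
    )
    removed = int((~keep).sum())
    return replace(table, counts=table.counts[keep].reset_index(drop=True)), removed


def remove_singletons(table: TagCountTable) -> tuple[TagCountTable, int]:
    """Drop tags whose combined count across both libraries is at most 1.

    Singletons (combined count exactly 1) are likely sequencing errors;
    all-zero rows are degenerate and dropped alongside.
    """
    combined = table.counts["count_ctl"] + table.counts["count_inf"]
    keep = combined > 1
    removed = int((~keep).sum())
    return replace(table, counts=table.counts[keep].reset_index(drop=True)), removed


def clean_table(
    table: TagCountTable,
    max_a_fraction: float = 0.8,
    max_terminal_a_run: int = 15,
) -> tuple[TagCountTable, dict[str, int]]:
    """Apply the standard cleaning cascade: poly-A removal then singleton removal."""
    n0 = len(table)
    table, n_polya = filter_polya(table, max_a_fraction, max_terminal_a_run)
    table, n_single = remove_singletons(table)
    report = {
        "input_tags": n0,
        "removed_polya": n_polya,
        "removed_singletons": n_single,
        "output_tags": len(table),
    }
    return table, report
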