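"""Readers and writers: Genepop genotype files, Newick trees, CSV tables.

Genepop is the de facto exchange format for microsatellite data: a title
line, one locus name per line (or a single comma-separated line), then one
or more ``Pop`` blocks of ``id ,  0102 0304 ...`` rows.  Allele codes are
either all 2-digit or all 3-digit within a file; 00/000 marks a missing
allele.  CSV tables use comma separators, '.' decimals, UTF-8 and a
mandatory header row.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .datatypes import (
    AvailabilityTable,
    GenotypeTable,
    HabitatUseTable,
    TranslocationTable,
    ValidationError,
    HABITAT_CLASSES,
)


class ParseError(ValidationError):
    """Malformed input file; the message names the offending line."""


# ---------------------------------------------------------------------------
# Genepop


def read_genepop(path: str | Path) -> GenotypeTable:
    """Parse a Genepop file into a :class:`GenotypeTable`.

    Accepts 2- and 3-digit allele encodings (auto-detected, mixing
    rejected), case-insensitive ``Pop`` markers, and both locus-per-line
    and comma-separated locus headers.  Pop blocks become the table's
    population labels ("pop1", "pop2", ...).
    """
    lines = Path(path).read_text(encoding="utf-8").splitlines()
    if len(lines) < 3:
        raise ParseError("genepop file too short: need title, loci and a Pop block")

    is_pop = lambda s: s.strip().lower() == "pop"
    loci: list[str] = []
    i = 1
    while i < len(lines) and not is_pop(lines[i]):
        chunk = lines[i].strip()
        if chunk:
            loci.extend(x.strip() for x in chunk.split(",") if x.strip())
        i += 1
    if not loci:
        raise ParseError("no locus names before the first Pop line")
    if i == len(lines):
        raise ParseError("no Pop block found")

    ids, pops, rows = [], [], []
    widths: set[int] = set()
    pop_idx = 0
    for lineno in range(i, len(lines)):
        raw = lines[lineno]
        if not raw.strip():
            continue
        if is_pop(raw):
            pop_idx += 1
            continue
        if "," not in raw:
            raise ParseError(f"line {lineno + 1}: missing ',' id separator")
        ind, geno = raw.split(",", 1)
        fields = geno.split()
        if len(fields) != len(loci):
            raise ParseError(
                f"line {lineno + 1}: {len(fields)} genotypes for "
                f"{len(loci)} loci"
            )
        pair_row = []
        for f in fields:
            if not re.fullmatch(r"\d+", f) or len(f) not in (4, 6):
                raise ParseError(
                    f"line {lineno + 1}: bad genotype field {f!r}"
                )
            w = len(f) // 2
            widths.add(w)
            pair_row.append((int(f[:w]), int(f[w:])))
        ids.append(ind.strip())
        pops.append(f"pop{pop_idx}")
        rows.append(pair_row)

    if len(widths) > 1:
        raise ParseError("mixed 2- and 3-digit allele encodings in one file")
    if not rows:
        raise ParseError("Pop block contains no individuals")

    alleles = np.array(rows, dtype=np.int64)
    return GenotypeTable(ids, loci, alleles, populations=pops)


def write_genepop(table: GenotypeTable, path: str | Path,
                  title: str = "bearlink synthetic genotypes") -> None:
    """Write a GenotypeTable as Genepop with 3-digit allele codes."""
    if table.alleles.max(initial=0) > 999:
        raise ValidationError("allele codes exceed 3-digit Genepop encoding")
    out = [title]
    out.extend(table.loci)
    pops = table.populations or ["pop1"] * table.n_individuals
    prev = None
    for i, ind in enumerate(table.ids):
        if pops[i] != prev:
            out.append("Pop")
            prev = pops[i]
        geno = " ".join(
            f"{a:03d}{b:03d}" for a, b in table.alleles[i]
        )
        out.append(f"{ind} ,  {geno}")
    Path(path).write_text("\n".join(out) + "\n", encoding="utf-8")


# ---------------------------------------------------------------------------
# Trees / Newick


@dataclass
class TreeNode:
    """Minimal rooted-representation tree node with branch lengths.

    An unrooted neighbor-joining tree is represented by an unnamed root of
    degree >= 3.  Children keep their insertion order; the Newick writer
    emits them in that order, which the builders keep deterministic.
    """

    name: str | None = None
    length: float | None = None
    children: list["TreeNode"] = field(default_factory=list)

    @property
    def is_leaf(self) -> bool:
        return not self.children

    def leaves(self) -> list["TreeNode"]:
        if self.is_leaf:
            return [self]
        out: list[TreeNode] = []
        for c in self.children:
            out.extend(c.leaves())
        return out


def _fmt_len(x: float) -> str:
    return format(x, "g")


def write_newick(tree: TreeNode) -> str:
    """Serialise a tree to a Newick string with branch lengths.

    Alphanumeric leaf names need no quoting; unnamed leaves are rejected.
    """

    def render(node: TreeNode, with_length: bool) -> str:
        if node.is_leaf:
            if not node.name:
                raise ValidationError("unnamed leaf cannot be written to Newick")
            s = node.name
        else:
            s = "(" + ",".join(render(c, True) for c in node.children) + ")"
            if node.name:
                s += node.name
        if with_length and node.length is not None:
            s += f":{_fmt_len(node.length)}"
        return s

    return render(tree, False) + ";"


def read_newick(text: str) -> TreeNode:
    """Parse a Newick string (names and branch lengths only)."""
    pos = 0
    s = text.strip()
    if not s.endswith(";"):
        raise ParseError("Newick string must end with ';'")
    s = s[:-1]

    def parse() -> TreeNode:
        nonlocal pos
        node = TreeNode()
        if pos < len(s) and s[pos] == "(":
            pos += 1
            while True:
                node.children.append(parse())
                if pos >= len(s):
                    raise ParseError("unbalanced parentheses in Newick")
                if s[pos] == ",":
                    pos += 1
                    continue
                if s[pos] == ")":
                    pos += 1
                    break
        m = re.match(r"[^,():;]*", s[pos:])
        if m and m.group():
            node.name = m.group()
            pos += len(m.group())
        if pos < len(s) and s[pos] == ":":
            pos += 1
            m = re.match(r"[-+0-9.eE]+", s[pos:])
            if not m:
                raise ParseError("missing branch length after ':'")
            node.length = float(m.group())
            pos += len(m.group())
        return node

    root = parse()
    if pos != len(s):
        raise ParseError(f"trailing characters in Newick at offset {pos}")
    return root


# ---------------------------------------------------------------------------
# CSV tables


def write_csv(df: pd.DataFrame, path: str | Path) -> None:
    df.to_csv(path, index=False)


def read_csv(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path)


def write_habitat_use(use: HabitatUseTable, path: str | Path) -> None:
    write_csv(use.to_frame(), path)


def read_habitat_use(path: str | Path) -> HabitatUseTable:
    df = read_csv(path)
    counts = df["fix_count"].to_numpy() if "fix_count" in df.columns else None
    return HabitatUseTable(
        df["id"].astype(str).tolist(),
        df[list(HABITAT_CLASSES)].to_numpy(float),
        fix_counts=counts,
    )


def write_availability(av: AvailabilityTable, path: str | Path) -> None:
    write_csv(av.to_frame(), path)


def read_availability(path: str | Path) -> AvailabilityTable:
    df = read_csv(path)
    return AvailabilityTable(
        df["unit"].astype(str).tolist(),
        df[list(HABITAT_CLASSES)].to_numpy(float),
        df["point_count"].to_numpy(),
    )


def write_translocations(t: TranslocationTable, path: str | Path) -> None:
    write_csv(t.events, path)


def read_translocations(path: str | Path) -> TranslocationTable:
    return TranslocationTable(read_csv(path))


def write_pairwise(ids: list[str], values: np.ndarray, path: str | Path) -> None:
    """Write a square matrix as CSV with an id header row and column."""
    df = pd.DataFrame(values, index=ids, columns=ids)
    df.to_csv(path, index_label="id")


def read_pairwise(path: str | Path) -> tuple[list[str], np.ndarray]:
    df = pd.read_csv(path, index_col=0)
    return [str(c) for c in df.columns], df.to_numpy(float)
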