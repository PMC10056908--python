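"""Readers and writers for character matrices (NEXUS, TNT, plain table) and
Newick trees.

NEXUS documents are parsed with :mod:`dendropy`; the TNT ``xread`` dialect and
the plain tab/comma-separated table are parsed directly (one single-digit
state token per cell, ``?`` missing, ``-`` inapplicable).  Trees are carried
as :class:`dendropy.Tree` objects throughout the package.
"""

from __future__ import annotations

import io as _io
import re

import dendropy
import numpy as np

from .matrix import (
    CharacterMatrix,
    MatrixFormatError,
    MAX_STATE,
    code_to_token,
    token_to_code,
)

_FORMATS = ("nexus", "tnt", "table")


def _as_text(source) -> str:
    if isinstance(source, bytes):
        return source.decode("utf-8")
    if isinstance(source, str):
        return source
    data = source.read()
    if isinstance(data, bytes):
        data = data.decode("utf-8")
    return data


def _rows_to_matrix(rows: list[tuple[str, str]]) -> CharacterMatrix:
    """Build a validated matrix from (taxon, token-string) rows."""
    if not rows:
        raise MatrixFormatError("document contains no taxon rows")
    ncol = len(rows[0][1])
    taxa, cells = [], []
    for taxon, tokens in rows:
        if len(tokens) != ncol:
            raise MatrixFormatError(
                f"ragged row for taxon {taxon!r}: {len(tokens)} cells, expected {ncol}"
            )
        try:
            cells.append([token_to_code(t) for t in tokens])
        except MatrixFormatError as e:
            raise MatrixFormatError(f"taxon {taxon!r}: {e}") from None
        taxa.append(taxon)
    return CharacterMatrix(taxa, np.array(cells, dtype=np.int8))


# ---------------------------------------------------------------- NEXUS

def _read_nexus(text: str) -> CharacterMatrix:
    try:
        dm = dendropy.StandardCharacterMatrix.get(data=text, schema="nexus")
    except Exception as e:  # dendropy raises several error types
        raise MatrixFormatError(f"NEXUS parse error: {e}") from None
    rows = []
    for tax in dm.taxon_namespace:
        tokens = "".join(str(c.symbol) for c in dm[tax])
        rows.append((tax.label, tokens))
    return _rows_to_matrix(rows)


def _write_nexus(m: CharacterMatrix) -> str:
    buf = _io.StringIO()
    buf.write("#NEXUS\n\nBEGIN DATA;\n")
    buf.write(f"DIMENSIONS NTAX={m.n_taxa} NCHAR={m.n_characters};\n")
    symbols = "".join(str(s) for s in range(MAX_STATE + 1))
    buf.write(f'FORMAT DATATYPE=STANDARD SYMBOLS="{symbols}" MISSING=? GAP=-;\n')
    buf.write("MATRIX\n")
    width = max(len(t) for t in m.taxa) + 2
    for i, t in enumerate(m.taxa):
        label = f"'{t}'" if re.search(r"\s", t) else t
        row = "".join(code_to_token(int(c)) for c in m.states[i])
        buf.write(f"{label:<{width}}{row}\n")
    buf.write(";\nEND;\n")
    return buf.getvalue()


# ---------------------------------------------------------------- TNT xread

def _read_tnt(text: str) -> CharacterMatrix:
    body = text.strip()
    if not body:
        raise MatrixFormatError("empty TNT document")
    mobj = re.search(r"xread\s*(?:'[^']*'\s*)?(\d+)\s+(\d+)(.*)", body, re.S | re.I)
    if not mobj:
        raise MatrixFormatError("no xread block found")
    nchar, ntax = int(mobj.group(1)), int(mobj.group(2))
    block = mobj.group(3)
    end = block.find(";")
    if end < 0:
        raise MatrixFormatError("xread block not terminated by ';'")
    rows = []
    for line in block[:end].strip().splitlines():
        line = line.strip()
        if not line:
            continue
        parts = line.split(None, 1)
        if len(parts) != 2:
            raise MatrixFormatError(f"malformed TNT row: {line!r}")
        name, tokens = parts
        rows.append((name.replace("_", " "), tokens.replace(" ", "")))
    if len(rows) != ntax:
        raise MatrixFormatError(f"xread declares {ntax} taxa but {len(rows)} rows found")
    m = _rows_to_matrix(rows)
    if m.n_characters != nchar:
        raise MatrixFormatError(
            f"xread declares {nchar} characters but rows have {m.n_characters}"
        )
    return m


def _write_tnt(m: CharacterMatrix) -> str:
    buf = _io.StringIO()
    buf.write(f"xread\n{m.n_characters} {m.n_taxa}\n")
    width = max(len(t) for t in m.taxa) + 2
    for i, t in enumerate(m.taxa):
        row = "".join(code_to_token(int(c)) for c in m.states[i])
        buf.write(f"{t.replace(' ', '_'):<{width}}{row}\n")
    buf.write(";\n")
    return buf.getvalue()


# ---------------------------------------------------------------- plain table

def _read_table(text: str) -> CharacterMatrix:
    lines = [ln for ln in text.splitlines() if ln.strip()]
    if not lines:
        raise MatrixFormatError("empty table document")
    sep = "\t" if "\t" in lines[0] else ","
    header = lines[0].split(sep)
    rows = []
    for ln in lines[1:]:
        parts = [p.strip() for p in ln.split(sep)]
        if len(parts) != len(header):
            raise MatrixFormatError(
                f"ragged row for taxon {parts[0]!r}: {len(parts) - 1} cells, "
                f"expected {len(header) - 1}"
            )
        rows.append((parts[0], "".join(parts[1:])))
    return _rows_to_matrix(rows)


def _write_table(m: CharacterMatrix) -> str:
    buf = _io.StringIO()
    buf.write("taxon\t" + "\t".join(str(j) for j in range(m.n_characters)) + "\n")
    for i, t in enumerate(m.taxa):
        buf.write(t + "\t" + "\t".join(code_to_token(int(c)) for c in m.states[i]) + "\n")
    return buf.getvalue()


# ---------------------------------------------------------------- public API

def read_matrix(source, format: str = "table") -> CharacterMatrix:
    """Read a character matrix from a stream, path-less text, or bytes.

    Parameters
    ----------
    source:
        Text, bytes, or an open file-like object.
    format:
        One of ``"nexus"``, ``"tnt"``, ``"table"``.
    """
    if format not in _FORMATS:
        raise ValueError(f"unknown format {format!r}; expected one of {_FORMATS}")
    text = _as_text(source)
    if not text.strip():
        raise MatrixFormatError("empty document")
    return {"nexus": _read_nexus, "tnt": _read_tnt, "table": _read_table}[format](text)


def write_matrix(matrix: CharacterMatrix, format: str = "table") -> str:
    """Serialize a matrix to the named dialect; round-trips cell-identically."""
    if format not in _FORMATS:
        raise ValueError(f"unknown format {format!r}; expected one of {_FORMATS}")
    return {"nexus": _write_nexus, "tnt": _write_tnt, "table": _write_table}[format](matrix)


def read_tree(source, taxon_namespace: dendropy.TaxonNamespace | None = None) -> dendropy.Tree:
    """Parse a Newick tree (multifurcations allowed, duplicates rejected)."""
    text = _as_text(source)
    try:
        tree = dendropy.Tree.get(
            data=text,
            schema="newick",
            taxon_namespace=taxon_namespace,
            preserve_underscores=True,
        )
    except Exception as e:
        raise ValueError(f"Newick parse error: {e}") from None
    labels = [lf.taxon.label for lf in tree.leaf_node_iter()]
    if len(labels) != len(set(labels)):
        raise ValueError("duplicate leaf labels in tree")
    return tree


def write_tree(tree: dendropy.Tree) -> str:
    return tree.as_string(
        schema="newick", suppress_rooting=True, unquoted_underscores=True
    ).strip()
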