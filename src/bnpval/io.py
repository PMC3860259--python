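"""Plain-text file formats for networks and time series.

Network file (``.bnp``)::

    n=10 p=0.01
    gene=1 regs=3,5,6 out=00101101
    ...

PBN files carry an extra header ``q=... c=0.5,0.5`` and one ``context``
line before each gene block.  Time series are TSV, one 0/1 row per time
point, one column per gene, with a blank line separating series.
"""

from __future__ import annotations

from pathlib import Path
from typing import Sequence

import numpy as np

from .network import BNp, PBN, TruthTable
from .generate import TimeSeries

__all__ = [
    "ParseError",
    "read_bnp",
    "write_bnp",
    "read_pbn",
    "write_pbn",
    "read_timeseries",
    "write_timeseries",
]


class ParseError(ValueError):
    """Malformed network or time-series file."""


def _parse_fields(line: str, lineno: int) -> dict[str, str]:
    fields = {}
    for tok in line.split():
        if "=" not in tok:
            raise ParseError(f"line {lineno}: expected key=value tokens, got {tok!r}")
        key, val = tok.split("=", 1)
        fields[key] = val
    return fields


def _parse_gene_line(fields: dict[str, str], lineno: int) -> TruthTable:
    try:
        gene = int(fields["gene"])
        regs = tuple(int(r) for r in fields["regs"].split(","))
        bits = fields["out"]
    except (KeyError, ValueError) as exc:
        raise ParseError(f"line {lineno}: bad gene line ({exc})") from exc
    if set(bits) - {"0", "1"}:
        raise ParseError(f"line {lineno}: gene {gene}: non-binary output string")
    if len(bits) != 2 ** len(regs):
        raise ParseError(
            f"line {lineno}: gene {gene}: expected {2 ** len(regs)} output bits "
            f"for {len(regs)} regulators, got {len(bits)}"
        )
    return TruthTable(gene, regs, np.frombuffer(bits.encode(), dtype=np.uint8) - ord("0"))


def _read_lines(path: str | Path) -> list[tuple[int, str]]:
    raw = Path(path).read_text().splitlines()
    return [(i + 1, ln.strip()) for i, ln in enumerate(raw)
            if ln.strip() and not ln.strip().startswith("#")]


def read_bnp(path: str | Path) -> BNp:
    """Read a single-context network file."""
    lines = _read_lines(path)
    if not lines:
        raise ParseError(f"{path}: empty network file")
    lineno, header = lines[0]
    fields = _parse_fields(header, lineno)
    try:
        n, p = int(fields["n"]), float(fields["p"])
    except (KeyError, ValueError) as exc:
        raise ParseError(f"line {lineno}: bad header ({exc})") from exc
    tables = [_parse_gene_line(_parse_fields(ln, no), no) for no, ln in lines[1:]]
    if len(tables) != n:
        raise ParseError(f"{path}: header says n={n} but found {len(tables)} gene lines")
    tables.sort(key=lambda t: t.gene)
    try:
        return BNp(tuple(tables), p)
    except ValueError as exc:
        raise ParseError(f"{path}: {exc}") from exc


def write_bnp(net: BNp, path: str | Path) -> None:
    lines = [f"n={net.n} p={net.p!r}"]
    for t in net.tables:
        bits = "".join(str(int(b)) for b in t.outputs)
        lines.append(f"gene={t.gene} regs={','.join(map(str, t.regulators))} out={bits}")
    Path(path).write_text("\n".join(lines) + "\n")


def read_pbn(path: str | Path) -> PBN:
    """Read a multi-context network file (``q=``/``c=`` header, context blocks)."""
    lines = _read_lines(path)
    lineno, header = lines[0]
    fields = _parse_fields(header, lineno)
    try:
        n, p = int(fields["n"]), float(fields["p"])
        q = float(fields["q"])
        c = np.array([float(v) for v in fields["c"].split(",")])
    except (KeyError, ValueError) as exc:
        raise ParseError(f"line {lineno}: bad PBN header ({exc})") from exc
    contexts: list[list[TruthTable]] = []
    for no, ln in lines[1:]:
        if ln == "context":
            contexts.append([])
            continue
        if not contexts:
            raise ParseError(f"line {no}: gene line before any 'context' marker")
        contexts[-1].append(_parse_gene_line(_parse_fields(ln, no), no))
    try:
        bnps = tuple(
            BNp(tuple(sorted(tabs, key=lambda t: t.gene)), p) for tabs in contexts
        )
        pbn = PBN(bnps, q, c)
    except ValueError as exc:
        raise ParseError(f"{path}: {exc}") from exc
    if pbn.n != n:
        raise ParseError(f"{path}: header says n={n} but contexts have n={pbn.n}")
    return pbn


def write_pbn(pbn: PBN, path: str | Path) -> None:
    c = ",".join(repr(float(v)) for v in pbn.c)
    lines = [f"n={pbn.n} p={pbn.contexts[0].p!r} q={pbn.q!r} c={c}"]
    for b in pbn.contexts:
        lines.append("context")
        for t in b.tables:
            bits = "".join(str(int(v)) for v in t.outputs)
            lines.append(f"gene={t.gene} regs={','.join(map(str, t.regulators))} out={bits}")
    Path(path).write_text("\n".join(lines) + "\n")


def read_timeseries(path: str | Path) -> list[TimeSeries]:
    """Read TSV time series; blank lines separate independent series."""
    out: list[TimeSeries] = []
    block: list[list[int]] = []
    sid = 0
    for lineno, raw in enumerate(Path(path).read_text().splitlines(), start=1):
        line = raw.strip()
        if not line:
            if block:
                out.append(TimeSeries(np.array(block, dtype=np.uint8), series_id=sid))
                block, sid = [], sid + 1
            continue
        row = []
        for tok in line.split("\t"):
            if tok not in ("0", "1"):
                raise ParseError(f"line {lineno}: non-binary token {tok!r}")
            row.append(int(tok))
        if block and len(row) != len(block[0]):
            raise ParseError(f"line {lineno}: inconsistent gene count")
        block.append(row)
    if block:
        out.append(TimeSeries(np.array(block, dtype=np.uint8), series_id=sid))
    if not out:
        raise ParseError(f"{path}: no time series found")
    return out


def write_timeseries(series: Sequence[TimeSeries], path: str | Path) -> None:
    chunks = []
    for s in series:
        chunks.append("\n".join("\t".join(map(str, row)) for row in s.states))
    Path(path).write_text("\n\n".join(chunks) + "\n")
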