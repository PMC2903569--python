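"""Tabular input/output, panel harmonization and expression normalization.

Both input tables are tab-separated with a header row:

* methylation: ``site_id  chromosome  position  <line1> <line2> ...``
* expression:  ``probeset_id  gene  chromosome  start  end  <line1> ...``

Methylation values are percentages in [0, 100]; expression values arrive on
a logarithmic scale (log2 by convention for expression arrays) and are
de-logged and min–max normalized to [0, 100] across the whole data set so
the two modalities share a scale.
"""

from __future__ import annotations

import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd

from .datatypes import ExpressionProbeSet, MethylationSite, Panel, RankedGene

logger = logging.getLogger(__name__)

_MISSING = {"", "na", "nan", "null", "none", "."}

METH_META_COLS = ["site_id", "chromosome", "position"]
EXPR_META_COLS = ["probeset_id", "gene", "chromosome", "start", "end"]


def read_panel(path: str | Path) -> Panel:
    """Read a panel file: one cell line per row, optional tab-separated subtype."""
    lines: list[str] = []
    subtypes: list[str | None] = []
    for raw in Path(path).read_text().splitlines():
        raw = raw.strip()
        if not raw or raw.startswith("#"):
            continue
        parts = raw.split("\t")
        lines.append(parts[0])
        subtypes.append(parts[1] if len(parts) > 1 and parts[1] else None)
    if not lines:
        raise ValueError(f"panel file {path} lists no cell lines")
    st = tuple(subtypes) if any(s is not None for s in subtypes) else None
    return Panel(tuple(lines), st)


def _check_columns(cols: list[str], meta: list[str], panel: Panel, path: str | Path) -> None:
    if cols[: len(meta)] != meta:
        raise ValueError(
            f"{path}: header must start with {meta}, got {cols[:len(meta)]}"
        )
    have = set(cols[len(meta):])
    want = set(panel.cell_lines)
    extra, missing = sorted(have - want), sorted(want - have)
    if extra or missing:
        raise ValueError(
            f"{path}: cell-line columns do not match panel; "
            f"extra={extra}, missing={missing}"
        )


def read_methylation(path: str | Path, panel: Panel) -> list[MethylationSite]:
    """Read a methylation table, dropping sites without valid chromosome annotation.

    Rows with an empty/missing chromosome are dropped and counted (the count
    is logged); profiles are reordered to panel order; the result is sorted
    by (chromosome, position).  Malformed numeric fields raise with the
    1-based data line number.
    """
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    _check_columns(list(df.columns), METH_META_COLS, panel, path)
    value_cols = list(df.columns[len(METH_META_COLS):])
    order = [value_cols.index(c) for c in panel.cell_lines]

    sites: list[MethylationSite] = []
    n_dropped = 0
    for lineno, row in enumerate(df.itertuples(index=False), start=1):
        chrom = row.chromosome.strip()
        if chrom.lower() in _MISSING:
            n_dropped += 1
            continue
        try:
            pos = int(row.position)
        except ValueError:
            raise ValueError(f"{path}:{lineno}: malformed position {row.position!r}") from None
        vals = np.empty(len(value_cols))
        raw = row[len(METH_META_COLS):]
        for j, v in enumerate(raw):
            v = v.strip()
            if v.lower() in _MISSING:
                vals[j] = np.nan
                continue
            try:
                vals[j] = float(v)
            except ValueError:
                raise ValueError(
                    f"{path}:{lineno}: malformed methylation value {v!r} "
                    f"(cell line {value_cols[j]})"
                ) from None
        try:
            sites.append(MethylationSite(row.site_id, chrom, pos, vals[order]))
        except ValueError as e:
            raise ValueError(f"{path}:{lineno}: {e}") from None
    if n_dropped:
        logger.info("read_methylation: dropped %d site(s) without valid chromosome", n_dropped)
    sites.sort(key=lambda s: (s.chromosome, s.position, s.site_id))
    return sites


def read_methylation_bed(path: str | Path, panel: Panel) -> list[MethylationSite]:
    """BED-dialect reader: ``chrom  start(0-based)  end  site_id  <lines...>``.

    Positions convert to the internal 1-based convention (position = start + 1).
    """
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    cols = list(df.columns)
    meta = ["chrom", "start", "end", "site_id"]
    _check_columns(cols, meta, panel, path)
    value_cols = cols[len(meta):]
    order = [value_cols.index(c) for c in panel.cell_lines]
    sites = []
    for lineno, row in enumerate(df.itertuples(index=False), start=1):
        chrom = row.chrom.strip()
        if chrom.lower() in _MISSING:
            continue
        vals = np.array([float(v) for v in row[len(meta):]])
        sites.append(MethylationSite(row.site_id, chrom, int(row.start) + 1, vals[order]))
    sites.sort(key=lambda s: (s.chromosome, s.position, s.site_id))
    return sites


def read_expression(path: str | Path, panel: Panel) -> list[ExpressionProbeSet]:
    """Read an expression table; values are left on the input (log) scale.

    Probe sets are sorted by (chromosome, start).  An empty table returns an
    empty collection with a warning; start > end and non-numeric values raise.
    """
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    _check_columns(list(df.columns), EXPR_META_COLS, panel, path)
    value_cols = list(df.columns[len(EXPR_META_COLS):])
    order = [value_cols.index(c) for c in panel.cell_lines]
    probesets: list[ExpressionProbeSet] = []
    for lineno, row in enumerate(df.itertuples(index=False), start=1):
        vals = np.empty(len(value_cols))
        for j, v in enumerate(row[len(EXPR_META_COLS):]):
            v = v.strip()
            if v.lower() in _MISSING:
                vals[j] = np.nan
                continue
            try:
                vals[j] = float(v)
            except ValueError:
                raise ValueError(
                    f"{path}:{lineno}: non-numeric expression value {v!r} "
                    f"(cell line {value_cols[j]})"
                ) from None
        try:
            probesets.append(
                ExpressionProbeSet(
                    row.probeset_id, row.gene, row.chromosome.strip(),
                    int(row.start), int(row.end), vals[order],
                )
            )
        except ValueError as e:
            raise ValueError(f"{path}:{lineno}: {e}") from None
    if not probesets:
        logger.warning("read_expression: %s contains no probe sets", path)
    probesets.sort(key=lambda p: (p.chromosome, p.start, p.probeset_id))
    return probesets


def write_methylation(path: str | Path, sites: list[MethylationSite], panel: Panel) -> None:
    """Write a methylation table in the reader's format (round-trip identity)."""
    with open(path, "w") as fh:
        fh.write("\t".join(METH_META_COLS + list(panel.cell_lines)) + "\n")
        for s in sites:
            vals = "\t".join(_fmt(v) for v in s.profile)
            fh.write(f"{s.site_id}\t{s.chromosome}\t{s.position}\t{vals}\n")


def write_expression(path: str | Path, probesets: list[ExpressionProbeSet], panel: Panel) -> None:
    with open(path, "w") as fh:
        fh.write("\t".join(EXPR_META_COLS + list(panel.cell_lines)) + "\n")
        for p in probesets:
            vals = "\t".join(_fmt(v) for v in p.profile)
            fh.write(f"{p.probeset_id}\t{p.gene}\t{p.chromosome}\t{p.start}\t{p.end}\t{vals}\n")


def _fmt(v: float) -> str:
    return "NA" if not np.isfinite(v) else repr(float(v))


def harmonize(meth_panel: Panel, expr_panel: Panel) -> Panel:
    """Intersection of two panels in deterministic sorted order.

    All downstream profiles must be subset/reordered to the result with
    :func:`subset_profiles`.  Subtype labels are carried over from whichever
    input panel provides them.
    """
    common = sorted(set(meth_panel.cell_lines) & set(expr_panel.cell_lines))
    if not common:
        raise ValueError("panels share no cell lines")
    subtypes = None
    for p in (meth_panel, expr_panel):
        if p.subtypes is not None:
            lookup = dict(zip(p.cell_lines, p.subtypes))
            subtypes = tuple(lookup.get(c) for c in common)
            break
    return Panel(tuple(common), subtypes)


def subset_profiles(items, source_panel: Panel, target_panel: Panel):
    """Reorder/subset every item's profile from source to target panel order."""
    idx = source_panel.index_of(list(target_panel.cell_lines))
    for it in items:
        it.profile = it.profile[idx]
    return items


def normalize_expression(
    probesets: list[ExpressionProbeSet], log_base: float = 2.0
) -> list[ExpressionProbeSet]:
    """De-log and min–max normalize expression to [0, 100] globally.

    Each value x becomes ``log_base ** x``; the global minimum over all probe
    sets and cell lines jointly maps to 0 and the global maximum to 100, so
    expression shares the methylation scale.  Monotone by construction.
    """
    if not probesets:
        return []
    decimal = [np.power(log_base, p.profile) for p in probesets]
    allv = np.concatenate([d[np.isfinite(d)] for d in decimal])
    if allv.size == 0:
        raise ValueError("expression data set has no finite values")
    gmin, gmax = allv.min(), allv.max()
    if gmax == gmin:
        raise ValueError("expression data set is constant; min-max normalization undefined")
    scale = 100.0 / (gmax - gmin)
    out = []
    for p, d in zip(probesets, decimal):
        out.append(
            ExpressionProbeSet(
                p.probeset_id, p.gene, p.chromosome, p.start, p.end,
                np.clip((d - gmin) * scale, 0.0, 100.0),  # guard rounding spill
            )
        )
    return out


def write_ranked_genes(path: str | Path, ranked: list[RankedGene], n_lines: int) -> None:
    """Ranked-gene table: gene, R, p_value, fit parameters and provenance.

    ``p_bh`` is a Benjamini–Hochberg adjusted p-value emitted as a
    supplementary column; the significance filter itself uses raw p-values.
    """
    rows = []
    for rg in ranked:
        rows.append(
            dict(
                gene=rg.gene, R=rg.R, p_value=rg.p_value,
                a=rg.fit.a, b=rg.fit.b, c=rg.fit.c,
                n_cell_lines=rg.fit.n_pairs,
                representative_id=f"{rg.region_id}.c{rg.cluster}",
                probeset_id=rg.probeset_id,
            )
        )
    df = pd.DataFrame(
        rows,
        columns=["gene", "R", "p_value", "a", "b", "c", "n_cell_lines",
                 "representative_id", "probeset_id"],
    )
    if len(df):
        from scipy.stats import false_discovery_control

        df["p_bh"] = false_discovery_control(df["p_value"].to_numpy(), method="bh")
    else:
        df["p_bh"] = pd.Series(dtype=float)
    df.to_csv(path, sep="\t", index=False, float_format="%.10g")


def write_metadata(path: str | Path, meta: dict) -> None:
    with open(path, "w") as fh:
        json.dump(meta, fh, indent=2, sort_keys=True, default=str)
        fh.write("\n")
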