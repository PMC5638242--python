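"""Readers and writers for the plain-text formats the pipeline exchanges.

All tables are tab-separated with a header row. Genomic intervals use BED
conventions (0-based half-open). Gene symbols are upper-cased on load so the
screen, expression and interactome layers share one symbol space.
"""

from __future__ import annotations

import pandas as pd

from .exceptions import ParseError

SCREEN_COLUMNS = ["inhibitor", "concentration", "arm", "replicate", "lu"]
SIRNA_COLUMNS = ["gene", "si", "fdr", "vehicle_survival", "validated"]
EXPRESSION_COLUMNS = ["gene", "fpkm_a", "fpkm_b", "fold_change", "q_value"]
INTERACTOME_COLUMNS = ["protein_a", "protein_b", "confidence"]
REGULATORY_COLUMNS = ["tf", "gene", "weight"]


def _require_columns(df: pd.DataFrame, cols: list[str], what: str) -> None:
    missing = [c for c in cols if c not in df.columns]
    if missing:
        raise ParseError(f"{what} table is missing columns {missing}")


def read_screen_table(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    _require_columns(df, SCREEN_COLUMNS, "screen")
    df["arm"] = df["arm"].str.lower()
    return df


def write_screen_table(df: pd.DataFrame, path) -> None:
    df.to_csv(path, sep="\t", index=False)


def read_activity_matrix(path) -> pd.DataFrame:
    """Wide inhibitor x kinase percent-activity matrix; NaN = not profiled."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    df.columns = [c.upper() for c in df.columns]
    return df


def write_activity_matrix(df: pd.DataFrame, path) -> None:
    df.to_csv(path, sep="\t", index_label="inhibitor")


def read_sirna_table(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    _require_columns(df, SIRNA_COLUMNS, "siRNA")
    df["gene"] = df["gene"].str.upper()
    df["validated"] = df["validated"].astype(bool)
    return df


def read_expression_table(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    _require_columns(df, EXPRESSION_COLUMNS, "expression")
    df["gene"] = df["gene"].str.upper()
    return df


def read_interactome(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    _require_columns(df, INTERACTOME_COLUMNS, "interactome")
    df["protein_a"] = df["protein_a"].str.upper()
    df["protein_b"] = df["protein_b"].str.upper()
    return df


def read_regulatory(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    _require_columns(df, REGULATORY_COLUMNS, "regulatory")
    df["tf"] = df["tf"].str.upper()
    df["gene"] = df["gene"].str.upper()
    return df


def write_table(df: pd.DataFrame, path) -> None:
    df.to_csv(path, sep="\t", index=False)


def write_input_nodes(nodes, path) -> None:
    """Persist InputNode lists (hit/DE tables) as TSV."""
    df = pd.DataFrame(
        [(n.name, n.commodity, n.capacity, n.direction or "") for n in nodes],
        columns=["name", "commodity", "capacity", "direction"],
    )
    df.to_csv(path, sep="\t", index=False)


def read_input_nodes(path) -> list:
    from .screens import InputNode

    df = pd.read_csv(path, sep="\t", keep_default_na=False)
    return [
        InputNode(
            str(r["name"]).upper(),
            str(r["commodity"]),
            float(r["capacity"]),
            str(r["direction"]) or None,
        )
        for _, r in df.iterrows()
    ]


def read_gene_list(path) -> set[str]:
    with open(path) as fh:
        return {line.strip().upper() for line in fh if line.strip()}


def write_gene_list(genes, path) -> None:
    with open(path, "w") as fh:
        for g in sorted(genes):
            fh.write(f"{g}\n")


def read_bed(path) -> pd.DataFrame:
    """Read a BED3+ file into (chrom, start, end[, name, score, strand]).

    Raises :class:`ParseError` with the 1-based line number on malformed rows.
    """
    rows = []
    names = ["chrom", "start", "end", "name", "score", "strand"]
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ParseError("BED row has fewer than 3 fields", lineno)
            try:
                start, end = int(fields[1]), int(fields[2])
            except ValueError:
                raise ParseError("BED start/end are not integers", lineno)
            if start < 0 or start >= end:
                raise ParseError(f"invalid interval [{start}, {end})", lineno)
            rows.append([fields[0], start, end] + fields[3:6])
    if not rows:
        return pd.DataFrame(columns=names[:3])
    width = max(len(r) for r in rows)
    rows = [r + [None] * (width - len(r)) for r in rows]
    return pd.DataFrame(rows, columns=names[:width])


def write_bed(df: pd.DataFrame, path) -> None:
    cols = [c for c in ["chrom", "start", "end", "name", "score", "strand"] if c in df.columns]
    df[cols].to_csv(path, sep="\t", index=False, header=False)


def read_tss_bed(path) -> pd.DataFrame:
    """TSS annotation as BED: start = TSS base, name = gene symbol."""
    df = read_bed(path)
    if "name" not in df.columns:
        raise ParseError("TSS BED requires a name (gene) column")
    out = pd.DataFrame(
        {
            "gene": df["name"].str.upper(),
            "chrom": df["chrom"],
            "tss": df["start"].astype(int),
            "strand": df["strand"] if "strand" in df.columns else "+",
        }
    )
    return out


def write_tss_bed(tss: pd.DataFrame, path) -> None:
    bed = pd.DataFrame(
        {
            "chrom": tss["chrom"],
            "start": tss["tss"],
            "end": tss["tss"] + 1,
            "name": tss["gene"],
            "score": 0,
            "strand": tss.get("strand", "+"),
        }
    )
    write_bed(bed, path)


def write_fasta(sequences: dict[str, str], path, width: int = 60) -> None:
    with open(path, "w") as fh:
        for name, seq in sequences.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


def read_fasta(path) -> dict[str, str]:
    from pyfaidx import Fasta

    return {name: str(rec[:]) for name, rec in Fasta(str(path)).items()}
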