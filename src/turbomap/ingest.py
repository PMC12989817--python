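"""Reading protein-groups tables and producing a log2 matrix.

Consumes the MaxQuant ``proteinGroups.txt`` dialect: one row per protein
group, ``LFQ intensity <sample>`` columns with 0 meaning "not
quantified", and ``+``-flag columns for potential contaminants, reverse
(decoy) hits and proteins only identified by a modification site.  Rows
carrying any of those flags are removed before quantitative analysis,
and intensities are log2 transformed with zeros becoming explicit
missing values.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import DataError, FormatError

log = logging.getLogger(__name__)

#: Group label of the non-transduced (bait-free) control line.
CONTROL_GROUP = "control"

# MaxQuant column names for the "+" flags, in file order.
FLAG_COLUMNS = {
    "contaminant": "Potential contaminant",
    "reverse": "Reverse",
    "only_by_site": "Only identified by site",
}


@dataclass
class IntensityTable:
    """Raw protein x sample LFQ intensities plus per-protein metadata.

    ``proteins`` is indexed by protein-group id and carries
    ``gene_symbol`` plus the three boolean flag columns; ``intensities``
    shares the index and has one non-negative float column per sample
    (0 = not quantified).
    """

    proteins: pd.DataFrame
    intensities: pd.DataFrame

    def __post_init__(self) -> None:
        if not self.proteins.index.equals(self.intensities.index):
            raise DataError("protein metadata and intensity rows do not align")
        if self.intensities.columns.duplicated().any():
            dupes = self.intensities.columns[self.intensities.columns.duplicated()]
            raise FormatError(f"duplicate sample names: {sorted(set(dupes))}")
        vals = self.intensities.to_numpy(dtype=float)
        if np.isnan(vals).any():
            raise DataError("intensity table contains non-numeric cells")
        if (vals < 0).any():
            raise DataError("negative intensities are not meaningful LFQ values")

    @property
    def samples(self) -> list[str]:
        return list(self.intensities.columns)

    def __len__(self) -> int:
        return len(self.proteins)


@dataclass
class SampleDesign:
    """Maps each sample to (group, assay, replicate).

    ``assay`` is ``"AP"`` (streptavidin affinity purification) or
    ``"bulk"`` (whole-cell proteome).
    """

    table: pd.DataFrame

    def __post_init__(self) -> None:
        required = {"sample_id", "group", "assay", "replicate"}
        missing = required - set(self.table.columns)
        if missing:
            raise FormatError(f"design table lacks columns: {sorted(missing)}")
        if self.table["sample_id"].duplicated().any():
            raise FormatError("duplicate sample_id in design table")

    def samples(self, group=None, assay: str | None = None) -> list[str]:
        """Sample ids matching a group (str or list of str) and/or assay."""
        t = self.table
        if group is not None:
            groups = [group] if isinstance(group, str) else list(group)
            t = t[t["group"].isin(groups)]
        if assay is not None:
            t = t[t["assay"] == assay]
        return list(t["sample_id"])

    @property
    def groups(self) -> list[str]:
        return list(dict.fromkeys(self.table["group"]))

    def cohorts(self) -> list[tuple[str, str, list[str]]]:
        """(group, assay, sample ids) for every experimental cohort."""
        out = []
        for (g, a), sub in self.table.groupby(["group", "assay"], sort=False):
            out.append((g, a, list(sub["sample_id"])))
        return out


@dataclass
class LogMatrix:
    """log2-intensity matrix with explicit missingness (NaN).

    ``transform_log`` records the ordered list of transforms applied so
    any derived result can state its provenance.
    """

    values: pd.DataFrame
    gene_symbols: pd.Series
    transform_log: list[str] = field(default_factory=list)

    def with_values(self, values: pd.DataFrame, transform: str) -> "LogMatrix":
        return LogMatrix(values, self.gene_symbols.loc[values.index],
                         self.transform_log + [transform])

    @property
    def samples(self) -> list[str]:
        return list(self.values.columns)

    def n_missing(self) -> int:
        return int(self.values.isna().to_numpy().sum())


def read_protein_groups(path, intensity_prefix: str = "LFQ intensity ") -> IntensityTable:
    """Read a MaxQuant-style proteinGroups TSV into an :class:`IntensityTable`.

    Sample names are the intensity column headers with ``intensity_prefix``
    stripped.  ``+`` in a flag column sets the corresponding boolean.
    Tolerates LF and CRLF line endings (pandas handles both).
    """
    path = Path(path)
    if not path.exists():
        raise FormatError(f"no such file: {path}")
    with open(path, encoding="utf-8") as fh:
        header = fh.readline().rstrip("\r\n").split("\t")
    raw_icols = [c for c in header if c.startswith(intensity_prefix)]
    if len(set(raw_icols)) != len(raw_icols):
        raise FormatError(f"{path.name}: duplicate sample names in intensity "
                          "columns")
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    icols = [c for c in df.columns if c.startswith(intensity_prefix)]
    if not icols:
        raise FormatError(
            f"{path.name}: no columns match intensity prefix {intensity_prefix!r}")
    samples = [c[len(intensity_prefix):] for c in icols]
    if len(set(samples)) != len(samples):
        raise FormatError(f"{path.name}: duplicate sample names in intensity columns")

    if "Protein IDs" not in df.columns:
        raise FormatError(f"{path.name}: missing 'Protein IDs' column")
    index = pd.Index(df["Protein IDs"], name="protein_id")

    genes = df.get("Gene names", pd.Series([""] * len(df)))
    # Multi-gene groups are collapsed to the first (razor) entry.
    symbols = genes.fillna("").map(lambda s: s.split(";")[0].strip())
    n_multi = int(genes.fillna("").str.contains(";").sum())
    if n_multi:
        log.info("collapsed %d multi-gene protein groups to their first symbol", n_multi)

    proteins = pd.DataFrame({"gene_symbol": symbols.values}, index=index)
    for attr, col in FLAG_COLUMNS.items():
        flags = df.get(col, pd.Series([""] * len(df)))
        proteins[attr] = (flags.fillna("").str.strip() == "+").values

    try:
        inten = df[icols].apply(pd.to_numeric, errors="raise")
    except (ValueError, TypeError) as exc:
        raise FormatError(f"{path.name}: malformed numeric intensity cell ({exc})") from exc
    inten.columns = samples
    inten.index = index
    return IntensityTable(proteins, inten.astype(float))


def filter_rows(table: IntensityTable) -> IntensityTable:
    """Drop rows flagged contaminant, reverse or only-identified-by-site."""
    flagged = table.proteins[list(FLAG_COLUMNS)].any(axis=1)
    n_removed = int(flagged.sum())
    log.info("filter_rows: removed %d/%d flagged rows", n_removed, len(table))
    kept = ~flagged
    if not kept.any():
        log.warning("filter_rows: all %d rows were flagged; table is empty", len(table))
    return IntensityTable(table.proteins.loc[kept].copy(),
                          table.intensities.loc[kept].copy())


def to_log2(table: IntensityTable) -> LogMatrix:
    """log2-transform intensities; zeros become missing (NaN)."""
    vals = table.intensities.to_numpy(dtype=float)
    if (vals < 0).any():
        raise DataError("cannot log2-transform negative intensities")
    with np.errstate(divide="ignore"):
        logged = np.where(vals > 0, np.log2(np.where(vals > 0, vals, 1.0)), np.nan)
    values = pd.DataFrame(logged, index=table.intensities.index,
                          columns=table.intensities.columns)
    return LogMatrix(values, table.proteins["gene_symbol"].copy(), ["log2"])


def read_gene_list(path) -> set[str]:
    """Read a one-symbol-per-line gene list, uppercased and deduplicated.

    Blank lines and ``#`` comment lines are skipped; an empty result only
    triggers a warning (the intersection downstream is then empty).
    """
    out: set[str] = set()
    with open(path, encoding="utf-8") as fh:
        for line in fh:
            sym = line.strip()
            if not sym or sym.startswith("#"):
                continue
            out.add(sym.upper())
    if not out:
        log.warning("gene list %s is empty", path)
    return out


def read_design(path) -> SampleDesign:
    """Read a sample-design TSV (sample_id, group, assay, replicate)."""
    df = pd.read_csv(path, sep="\t", dtype={"sample_id": str, "group": str,
                                            "assay": str})
    return SampleDesign(df)
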