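"""Community tables, sample metadata, taxonomy, and their plumbing.

The universal currency of the pipeline is the :class:`CommunityTable`: a
taxa x samples matrix of read counts (or relative abundances) with opaque
taxon and sample identifiers.  Sample metadata lives in a plain pandas
DataFrame indexed by sample id (the "sample frame"), taxonomy in a
DataFrame indexed by taxon id with one column per rank.

Counts enter the pipeline from TSV (taxa rows, sample columns) or from a
dense BIOM-style JSON document; rarefaction, closure to relative
abundance, rank aggregation and prevalence filtering all happen here.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from ._errors import DataError, ValidationError

logger = logging.getLogger(__name__)

#: The taxonomic rank ladder used throughout, coarsest first.
RANKS = ("phylum", "class", "order", "family", "genus")

#: Cellar-age groups in increasing-age order, and the representative ages
#: (years) used when regressing against a numeric temporal axis: groups
#: cover <10 y, 10-50 y, ~100 y and ~300-400 y of continuous cellar use.
AGE_GROUPS = ("Aa", "Ab", "Ac", "Ad")
AGE_GROUP_YEARS = {"Aa": 5.0, "Ab": 30.0, "Ac": 100.0, "Ad": 350.0}

#: Longitude (production-region) groups, west to east.
LONGITUDE_GROUPS = ("La", "Lb", "Lc", "Ld")

UNASSIGNED = "unassigned"


@dataclass
class CommunityTable:
    """Taxa x samples abundance matrix.

    Parameters
    ----------
    data:
        DataFrame with taxon ids as index, sample ids as columns.  Values
        are non-negative; integers for counts, reals for relative
        abundances.
    is_relative:
        If True every sample column sums to 1 (tolerance 1e-9).
    """

    data: pd.DataFrame
    is_relative: bool = False

    def __post_init__(self) -> None:
        self.data = self.data.copy()
        self.data.index = self.data.index.astype(str)
        self.data.columns = self.data.columns.astype(str)
        self.validate()

    # -- invariants --------------------------------------------------

    def validate(self) -> None:
        idx, cols = self.data.index, self.data.columns
        if idx.has_duplicates:
            dups = idx[idx.duplicated()].unique().tolist()
            raise ValidationError(f"duplicate taxon id(s): {dups}")
        if cols.has_duplicates:
            dups = cols[cols.duplicated()].unique().tolist()
            raise ValidationError(f"duplicate sample id(s): {dups}")
        values = self.data.to_numpy()
        if not np.issubdtype(values.dtype, np.number):
            raise ValidationError("community table values must be numeric")
        if np.isnan(values).any():
            raise ValidationError("community table contains missing values")
        if (values < 0).any():
            ti, si = np.argwhere(values < 0)[0]
            raise ValidationError(
                f"negative value at taxon {idx[ti]!r}, sample {cols[si]!r}"
            )
        if self.is_relative and values.size:
            # Columns sum to 1 when freshly closed; taxon filtering may
            # leave a sub-closed table, so the class enforces only <= 1.
            sums = values.sum(axis=0)
            bad = np.flatnonzero(sums > 1.0 + 1e-9)
            if bad.size:
                raise ValidationError(
                    f"relative-abundance columns must sum to <= 1; sample "
                    f"{cols[bad[0]]!r} sums to {sums[bad[0]]!r}"
                )

    # -- accessors ---------------------------------------------------

    @property
    def taxon_ids(self) -> list[str]:
        return self.data.index.tolist()

    @property
    def sample_ids(self) -> list[str]:
        return self.data.columns.tolist()

    @property
    def n_taxa(self) -> int:
        return self.data.shape[0]

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    def matrix(self) -> np.ndarray:
        """Values as a taxa x samples ndarray (float)."""
        return self.data.to_numpy(dtype=float)

    def sample_sums(self) -> pd.Series:
        return self.data.sum(axis=0)

    def select_samples(self, sample_ids) -> "CommunityTable":
        return CommunityTable(self.data[list(sample_ids)], self.is_relative)

    def select_taxa(self, taxon_ids) -> "CommunityTable":
        return CommunityTable(self.data.loc[list(taxon_ids)], self.is_relative)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, CommunityTable):
            return NotImplemented
        return (
            self.is_relative == other.is_relative
            and self.data.shape == other.data.shape
            and self.data.index.equals(other.data.index)
            and self.data.columns.equals(other.data.columns)
            and np.allclose(self.data.to_numpy(float), other.data.to_numpy(float),
                            rtol=0.0, atol=1e-12)
        )


# ---------------------------------------------------------------------
# I/O
# ---------------------------------------------------------------------

def read_community(path, format: str = "tsv") -> CommunityTable:
    """Read an OTU table.

    ``tsv``: taxa rows / sample columns, header row of sample ids, first
    column taxon ids.  ``biom-json``: dense BIOM-style JSON with ``rows``,
    ``columns`` and a dense ``data`` matrix.
    """
    if format == "tsv":
        df = pd.read_csv(path, sep="\t", index_col=0)
        if df.columns.size == 0:
            raise ValidationError(f"{path}: no sample columns in header")
        try:
            df = df.apply(pd.to_numeric)
        except (ValueError, TypeError) as exc:
            raise ValidationError(f"{path}: non-numeric value ({exc})") from exc
    elif format == "biom-json":
        with open(path) as fh:
            doc = json.load(fh)
        try:
            taxa = [r["id"] for r in doc["rows"]]
            samples = [c["id"] for c in doc["columns"]]
            data = np.asarray(doc["data"], dtype=float)
        except (KeyError, TypeError) as exc:
            raise ValidationError(f"{path}: malformed BIOM-style JSON ({exc})") from exc
        if data.shape != (len(taxa), len(samples)):
            raise ValidationError(
                f"{path}: data shape {data.shape} does not match "
                f"{len(taxa)} rows x {len(samples)} columns"
            )
        df = pd.DataFrame(data, index=taxa, columns=samples)
    else:
        raise ValidationError(f"unknown community table format {format!r}")
    is_relative = bool(
        df.size
        and not np.allclose(df.to_numpy(float) % 1.0, 0.0)
        and np.allclose(df.sum(axis=0).to_numpy(), 1.0, atol=1e-9)
    )
    return CommunityTable(df, is_relative=is_relative)


def write_community(table: CommunityTable, path, format: str = "tsv") -> None:
    if format == "tsv":
        df = table.data
        if not table.is_relative and np.allclose(df.to_numpy(float) % 1.0, 0.0):
            df = df.astype(np.int64)
        df.to_csv(path, sep="\t", index_label="taxon_id")
    elif format == "biom-json":
        doc = {
            "format": "biom-style dense json",
            "matrix_type": "dense",
            "shape": [table.n_taxa, table.n_samples],
            "rows": [{"id": t} for t in table.taxon_ids],
            "columns": [{"id": s} for s in table.sample_ids],
            "data": table.matrix().tolist(),
        }
        with open(path, "w") as fh:
            json.dump(doc, fh)
    else:
        raise ValidationError(f"unknown community table format {format!r}")


def read_taxonomy(path) -> pd.DataFrame:
    """Taxonomy TSV: columns taxon_id, phylum, class, order, family, genus."""
    df = pd.read_csv(path, sep="\t", index_col=0, dtype=str)
    df.index = df.index.astype(str)
    missing = [r for r in RANKS if r not in df.columns]
    if missing:
        raise ValidationError(f"{path}: taxonomy missing rank column(s) {missing}")
    if df.index.has_duplicates:
        dups = df.index[df.index.duplicated()].unique().tolist()
        raise ValidationError(f"{path}: duplicate taxon id(s) {dups}")
    return df[list(RANKS)]


def write_taxonomy(taxonomy: pd.DataFrame, path) -> None:
    taxonomy.to_csv(path, sep="\t", index_label="taxon_id")


def read_sample_frame(path) -> pd.DataFrame:
    """Metadata TSV: sample_id, age_group, age_years, longitude_group, longitude_deg."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    df.index = df.index.astype(str)
    return validate_sample_frame(df)


def write_sample_frame(frame: pd.DataFrame, path) -> None:
    frame.to_csv(path, sep="\t", index_label="sample_id")


def validate_sample_frame(frame: pd.DataFrame) -> pd.DataFrame:
    if frame.index.has_duplicates:
        dups = frame.index[frame.index.duplicated()].unique().tolist()
        raise ValidationError(f"duplicate sample id(s) in metadata: {dups}")
    if "age_group" in frame.columns:
        bad = set(frame["age_group"].dropna()) - set(AGE_GROUPS)
        if bad:
            raise ValidationError(f"unknown age_group value(s): {sorted(bad)}")
        frame = frame.copy()
        frame["age_group"] = pd.Categorical(
            frame["age_group"], categories=AGE_GROUPS, ordered=True
        )
    if "longitude_group" in frame.columns:
        bad = set(frame["longitude_group"].dropna()) - set(LONGITUDE_GROUPS)
        if bad:
            raise ValidationError(f"unknown longitude_group value(s): {sorted(bad)}")
    return frame


def check_frame_covers(table: CommunityTable, frame: pd.DataFrame) -> None:
    """Every sample in the table must have a metadata row."""
    missing = [s for s in table.sample_ids if s not in frame.index]
    if missing:
        raise ValidationError(f"samples missing from metadata: {missing}")


def numeric_age(frame: pd.DataFrame, encoding: dict | None = None) -> pd.Series:
    """Numeric age per sample: ``age_years`` where present, otherwise the
    representative age of the sample's age group (configurable encoding)."""
    encoding = dict(AGE_GROUP_YEARS if encoding is None else encoding)
    mapped = frame["age_group"].astype(str).map(encoding)
    if "age_years" in frame.columns:
        years = pd.to_numeric(frame["age_years"], errors="coerce")
        mapped = years.fillna(mapped)
    return mapped.astype(float)


# ---------------------------------------------------------------------
# Transformations
# ---------------------------------------------------------------------

def rarefy(table: CommunityTable, depth: int, seed: int) -> CommunityTable:
    """Rarefy every sample to ``depth`` reads without replacement.

    Subsampling is multivariate hypergeometric, so each surviving column
    sums to exactly ``depth``.  Samples whose total is below the depth are
    dropped (with a logged warning), mirroring the usual minimum-count
    filter applied before rarefying.
    """
    if table.is_relative:
        raise ValidationError("rarefy requires a count table, not relative abundances")
    if depth <= 0:
        raise ValidationError(f"rarefaction depth must be positive, got {depth}")
    values = table.matrix()
    if not np.allclose(values % 1.0, 0.0):
        raise ValidationError("rarefy requires integer counts")
    counts = values.astype(np.int64)
    sums = counts.sum(axis=0)
    keep = sums >= depth
    dropped = [s for s, k in zip(table.sample_ids, keep) if not k]
    if dropped:
        logger.warning("rarefy: dropping %d sample(s) below depth %d: %s",
                       len(dropped), depth, dropped)
    if not keep.any():
        raise DataError(f"all samples are below rarefaction depth {depth}")
    rng = np.random.default_rng(seed)
    kept_ids = [s for s, k in zip(table.sample_ids, keep) if k]
    out = np.empty((table.n_taxa, len(kept_ids)), dtype=np.int64)
    for j, col in enumerate(counts[:, keep].T):
        out[:, j] = rng.multivariate_hypergeometric(col, depth)
    return CommunityTable(pd.DataFrame(out, index=table.taxon_ids, columns=kept_ids))


def to_relative(table: CommunityTable) -> CommunityTable:
    """Close each sample to relative abundance (columns sum to 1)."""
    values = table.matrix()
    sums = values.sum(axis=0)
    if (sums <= 0).any():
        empty = [s for s, t in zip(table.sample_ids, sums) if t <= 0]
        raise DataError(f"cannot normalize empty sample(s): {empty}")
    rel = values / sums
    return CommunityTable(
        pd.DataFrame(rel, index=table.taxon_ids, columns=table.sample_ids),
        is_relative=True,
    )


def aggregate(table: CommunityTable, taxonomy: pd.DataFrame, rank: str) -> CommunityTable:
    """Sum member taxa at ``rank``; taxa unassigned at that rank (or absent
    from the taxonomy) pool into an explicit ``unassigned`` row so that
    per-sample totals are conserved."""
    if rank not in RANKS:
        raise ValidationError(f"unknown rank {rank!r}; expected one of {RANKS}")
    labels = taxonomy[rank].reindex(table.data.index)
    n_unannotated = int(labels.isna().sum())
    if n_unannotated:
        logger.info("aggregate: %d taxa unassigned at rank %s pooled into %r",
                    n_unannotated, rank, UNASSIGNED)
    labels = labels.fillna(UNASSIGNED).replace("", UNASSIGNED)
    grouped = table.data.groupby(labels.to_numpy()).sum()
    grouped.index.name = rank
    return CommunityTable(grouped, is_relative=table.is_relative)


def filter_prevalence(
    table: CommunityTable, min_prevalence: float, min_mean_ra: float
) -> CommunityTable:
    """Keep taxa present in >= ``min_prevalence`` of samples AND with mean
    relative abundance >= ``min_mean_ra``.  Expects a relative table."""
    for name, frac in (("min_prevalence", min_prevalence), ("min_mean_ra", min_mean_ra)):
        if not 0.0 <= frac <= 1.0:
            raise ValidationError(f"{name} must be in [0, 1], got {frac}")
    if not table.is_relative:
        raise ValidationError("filter_prevalence expects a relative-abundance table")
    values = table.matrix()
    prevalence = (values > 0).mean(axis=1)
    mean_ra = values.mean(axis=1)
    keep = (prevalence >= min_prevalence) & (mean_ra >= min_mean_ra)
    removed = [t for t, k in zip(table.taxon_ids, keep) if not k]
    if removed:
        logger.info("filter_prevalence: removed %d / %d taxa", len(removed), table.n_taxa)
    return CommunityTable(table.data.loc[keep], is_relative=table.is_relative)
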