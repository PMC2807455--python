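"""Core data containers and TSV/Newick readers and writers.

All tabular formats are tab-separated UTF-8 with a header row. Taxon ids are
opaque strings (PhyloChip OTU ids such as ``"3821"``); samples are labelled
strings. Numeric output is printed with 6 significant digits.
"""

from __future__ import annotations

import io as _io
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import dendropy
import numpy as np
import pandas as pd

__all__ = [
    "FormatError",
    "ProbeCallTable",
    "TaxonAbundanceMatrix",
    "SampleGroups",
    "ScreenResult",
    "read_probe_call_table",
    "write_probe_call_table",
    "read_newick",
    "write_newick",
    "read_sample_groups",
    "write_sample_groups",
    "read_abundance_matrix",
    "write_abundance_matrix",
    "write_screen_table",
    "read_screen_table",
    "format_float",
]

#: significant digits for every numeric cell written by this package
FLOAT_DIGITS = 6


class FormatError(ValueError):
    """Raised when an input file violates the declared format or invariants."""


def format_float(x: float) -> str:
    """Render a float with :data:`FLOAT_DIGITS` significant digits."""
    if isinstance(x, (bool, np.bool_)):
        return str(bool(x))
    return f"{x:.{FLOAT_DIGITS}g}"


# ---------------------------------------------------------------------------
# Probe-call table
# ---------------------------------------------------------------------------

@dataclass
class ProbeCallTable:
    """Per taxon × sample probe-set summary from a 16S oligonucleotide array.

    Each taxon is interrogated by a probe set of ``probes_total[i]`` probes;
    ``probes_positive[i, j]`` of them scored positive in sample ``j`` and
    ``intensity[i, j]`` is the mean probe-set fluorescence (arbitrary
    fluorescence units, strictly positive).
    """

    taxon_ids: list[str]
    sample_ids: list[str]
    probes_total: np.ndarray          # (n_taxa,) int
    probes_positive: np.ndarray       # (n_taxa, n_samples) int
    intensity: np.ndarray             # (n_taxa, n_samples) float

    def __post_init__(self) -> None:
        self.taxon_ids = [str(t) for t in self.taxon_ids]
        self.sample_ids = [str(s) for s in self.sample_ids]
        self.probes_total = np.asarray(self.probes_total, dtype=int)
        self.probes_positive = np.asarray(self.probes_positive, dtype=int)
        self.intensity = np.asarray(self.intensity, dtype=float)
        n_t, n_s = len(self.taxon_ids), len(self.sample_ids)
        if len(set(self.taxon_ids)) != n_t:
            raise FormatError("duplicate taxon ids in probe-call table")
        if len(set(self.sample_ids)) != n_s:
            raise FormatError("duplicate sample ids in probe-call table")
        if self.probes_total.shape != (n_t,):
            raise FormatError("probes_total must have one entry per taxon")
        if self.probes_positive.shape != (n_t, n_s) or self.intensity.shape != (n_t, n_s):
            raise FormatError("probe matrices must be (n_taxa, n_samples)")
        if (self.probes_total <= 0).any():
            bad = self.taxon_ids[int(np.argmax(self.probes_total <= 0))]
            raise FormatError(f"taxon {bad!r}: probes_total must be positive")
        over = self.probes_positive > self.probes_total[:, None]
        if over.any():
            i, j = np.argwhere(over)[0]
            raise FormatError(
                f"taxon {self.taxon_ids[i]!r}, sample {self.sample_ids[j]!r}: "
                f"probes_positive={self.probes_positive[i, j]} exceeds "
                f"probes_total={self.probes_total[i]}"
            )
        if (self.probes_positive < 0).any():
            raise FormatError("probes_positive must be non-negative")
        if not np.all(self.intensity > 0):
            i, j = np.argwhere(~(self.intensity > 0))[0]
            raise FormatError(
                f"taxon {self.taxon_ids[i]!r}, sample {self.sample_ids[j]!r}: "
                "intensity must be strictly positive"
            )

    @property
    def shape(self) -> tuple[int, int]:
        return len(self.taxon_ids), len(self.sample_ids)


_PROBE_COLUMNS = ["taxon_id", "sample_id", "probes_total", "probes_positive", "intensity"]


def read_probe_call_table(path: str | Path) -> ProbeCallTable:
    """Read a long-format probe-call TSV.

    Columns: ``taxon_id  sample_id  probes_total  probes_positive  intensity``,
    one row per taxon × sample cell. Row order of first appearance is
    preserved for both taxa and samples.
    """
    path = Path(path)
    df = pd.read_csv(path, sep="\t", dtype={"taxon_id": str, "sample_id": str})
    missing = [c for c in _PROBE_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: missing columns {missing}")
    for col in ("probes_total", "probes_positive", "intensity"):
        vals = pd.to_numeric(df[col], errors="coerce")
        if vals.isna().any():
            row = int(vals.isna().idxmax())
            raise FormatError(f"{path}: non-numeric value in column {col!r}, row {row + 2}")
        df[col] = vals
    taxa = list(dict.fromkeys(df["taxon_id"]))
    samples = list(dict.fromkeys(df["sample_id"]))
    n_t, n_s = len(taxa), len(samples)
    if len(df) != n_t * n_s:
        raise FormatError(f"{path}: expected {n_t * n_s} rows (taxa × samples), found {len(df)}")
    t_idx = {t: i for i, t in enumerate(taxa)}
    s_idx = {s: j for j, s in enumerate(samples)}
    total = np.zeros(n_t, dtype=int)
    pos = np.zeros((n_t, n_s), dtype=int)
    inten = np.zeros((n_t, n_s), dtype=float)
    for rec in df.itertuples(index=False):
        i, j = t_idx[rec.taxon_id], s_idx[rec.sample_id]
        total[i] = int(rec.probes_total)
        pos[i, j] = int(rec.probes_positive)
        inten[i, j] = float(rec.intensity)
    return ProbeCallTable(taxa, samples, total, pos, inten)


def write_probe_call_table(table: ProbeCallTable, path: str | Path) -> None:
    """Write the long-format probe-call TSV read by :func:`read_probe_call_table`."""
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        fh.write("\t".join(_PROBE_COLUMNS) + "\n")
        for i, t in enumerate(table.taxon_ids):
            for j, s in enumerate(table.sample_ids):
                fh.write(
                    f"{t}\t{s}\t{table.probes_total[i]}\t"
                    f"{table.probes_positive[i, j]}\t{format_float(table.intensity[i, j])}\n"
                )


# ---------------------------------------------------------------------------
# Abundance matrix
# ---------------------------------------------------------------------------

@dataclass
class TaxonAbundanceMatrix:
    """Log-scale abundance with a presence mask — the analysis working matrix.

    ``abundance`` holds the log-transformed probe-set intensity for every
    retained taxon in every sample (including samples where the taxon fell
    below the presence threshold); ``present`` is the boolean presence call.
    Only taxa present in at least one sample are retained.
    """

    taxon_ids: list[str]
    sample_ids: list[str]
    abundance: np.ndarray   # (n_taxa, n_samples) float, log scale
    present: np.ndarray     # (n_taxa, n_samples) bool

    def __post_init__(self) -> None:
        self.taxon_ids = [str(t) for t in self.taxon_ids]
        self.sample_ids = [str(s) for s in self.sample_ids]
        self.abundance = np.asarray(self.abundance, dtype=float)
        self.present = np.asarray(self.present, dtype=bool)
        n_t, n_s = len(self.taxon_ids), len(self.sample_ids)
        if self.abundance.shape != (n_t, n_s) or self.present.shape != (n_t, n_s):
            raise FormatError("abundance and present must be (n_taxa, n_samples)")
        if len(set(self.taxon_ids)) != n_t or len(set(self.sample_ids)) != n_s:
            raise FormatError("duplicate ids in abundance matrix")
        if not np.isfinite(self.abundance[self.present]).all():
            raise FormatError("abundance must be finite wherever present")

    @property
    def detected_anywhere(self) -> np.ndarray:
        """Row-wise OR of the presence mask."""
        return self.present.any(axis=1)

    @property
    def shape(self) -> tuple[int, int]:
        return len(self.taxon_ids), len(self.sample_ids)

    def taxon_index(self, taxon_id: str) -> int:
        try:
            return self.taxon_ids.index(str(taxon_id))
        except ValueError:
            raise KeyError(f"taxon {taxon_id!r} not in matrix") from None

    def sample_index(self, sample_id: str) -> int:
        try:
            return self.sample_ids.index(str(sample_id))
        except ValueError:
            raise KeyError(f"sample {sample_id!r} not in matrix") from None

    def to_frames(self) -> tuple[pd.DataFrame, pd.DataFrame]:
        idx = pd.Index(self.taxon_ids, name="taxon_id")
        cols = pd.Index(self.sample_ids, name="sample_id")
        return (
            pd.DataFrame(self.abundance, index=idx, columns=cols),
            pd.DataFrame(self.present, index=idx, columns=cols),
        )


def write_abundance_matrix(matrix: TaxonAbundanceMatrix, abundance_path: str | Path,
                           presence_path: str | Path | None = None) -> None:
    """Write the wide abundance TSV and (optionally) the companion presence mask."""
    ab, pr = matrix.to_frames()
    ab.map(format_float).to_csv(abundance_path, sep="\t", lineterminator="\n")
    if presence_path is not None:
        pr.astype(int).to_csv(presence_path, sep="\t", lineterminator="\n")


def read_abundance_matrix(abundance_path: str | Path,
                          presence_path: str | Path) -> TaxonAbundanceMatrix:
    ab = pd.read_csv(abundance_path, sep="\t", index_col=0, dtype={0: str})
    pr = pd.read_csv(presence_path, sep="\t", index_col=0, dtype={0: str})
    ab.index = ab.index.astype(str)
    pr.index = pr.index.astype(str)
    if list(ab.index) != list(pr.index) or list(ab.columns) != list(pr.columns):
        raise FormatError("abundance and presence tables disagree on taxa or samples")
    return TaxonAbundanceMatrix(
        list(ab.index), list(ab.columns), ab.to_numpy(float), pr.to_numpy(bool)
    )


# ---------------------------------------------------------------------------
# Sample groups
# ---------------------------------------------------------------------------

HIGH, LOW, UNASSIGNED = "high", "low", "unassigned"


@dataclass
class SampleGroups:
    """Mapping of sample id to ``high`` / ``low`` / ``unassigned``."""

    labels: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for s, g in self.labels.items():
            if g not in (HIGH, LOW, UNASSIGNED):
                raise FormatError(f"sample {s!r}: unknown group {g!r}")

    @property
    def high(self) -> list[str]:
        return [s for s, g in self.labels.items() if g == HIGH]

    @property
    def low(self) -> list[str]:
        return [s for s, g in self.labels.items() if g == LOW]

    def require_two_groups(self) -> None:
        if len(self.high) < 2 or len(self.low) < 2:
            raise ValueError(
                f"two-group test needs ≥2 samples per group "
                f"(high={len(self.high)}, low={len(self.low)})"
            )


def read_sample_groups(path: str | Path) -> SampleGroups:
    df = pd.read_csv(path, sep="\t", dtype=str)
    if "sample_id" not in df.columns or "group" not in df.columns:
        raise FormatError(f"{path}: metadata needs columns sample_id, group")
    if df["sample_id"].duplicated().any():
        raise FormatError(f"{path}: duplicate sample ids")
    return SampleGroups(dict(zip(df["sample_id"], df["group"])))


def write_sample_groups(groups: SampleGroups, path: str | Path) -> None:
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        fh.write("sample_id\tgroup\n")
        for s, g in groups.labels.items():
            fh.write(f"{s}\t{g}\n")


# ---------------------------------------------------------------------------
# Newick trees
# ---------------------------------------------------------------------------

def read_newick(path: str | Path) -> dendropy.Tree:
    """Read a single rooted Newick tree with branch lengths.

    Duplicate tip labels and missing branch lengths are rejected; tip labels
    are preserved verbatim (no underscore munging).
    """
    path = Path(path)
    try:
        tree = dendropy.Tree.get(
            path=str(path),
            schema="newick",
            preserve_underscores=True,
            suppress_internal_node_taxa=True,
        )
    except Exception as exc:  # dendropy raises several error types
        raise FormatError(f"{path}: Newick parse error: {exc}") from exc
    return _validate_tree(tree, source=str(path))


def tree_from_string(newick: str) -> dendropy.Tree:
    """Parse a Newick string (same validation as :func:`read_newick`)."""
    try:
        tree = dendropy.Tree.get(
            data=newick,
            schema="newick",
            preserve_underscores=True,
            suppress_internal_node_taxa=True,
        )
    except Exception as exc:
        raise FormatError(f"Newick parse error: {exc}") from exc
    return _validate_tree(tree, source="<string>")


def _validate_tree(tree: dendropy.Tree, source: str) -> dendropy.Tree:
    tree.is_rooted = True
    labels = [leaf.taxon.label for leaf in tree.leaf_node_iter()]
    if len(labels) != len(set(labels)):
        dup = sorted({l for l in labels if labels.count(l) > 1})
        raise FormatError(f"{source}: duplicate tip labels {dup}")
    for node in tree.preorder_node_iter():
        if node is tree.seed_node:
            continue
        if node.edge.length is None:
            raise FormatError(f"{source}: tree has edges without branch lengths")
        if node.edge.length < 0:
            raise FormatError(f"{source}: negative branch length {node.edge.length}")
    return tree


def write_newick(tree: dendropy.Tree, path: str | Path) -> None:
    tree.write(path=str(path), schema="newick", suppress_rooting=True,
               unquoted_underscores=True)


def tip_labels(tree: dendropy.Tree) -> list[str]:
    return [leaf.taxon.label for leaf in tree.leaf_node_iter()]


# ---------------------------------------------------------------------------
# Screen results
# ---------------------------------------------------------------------------

@dataclass
class ScreenResult:
    """One taxon's record from a differential or correlation screen.

    ``statistic`` is a Welch t or a Pearson r; ``direction`` is ``up``/``down``
    for differential screens and ``positive``/``negative`` for correlation
    screens. Taxa with undefined statistics (zero variance) carry NaN p/q,
    ``excluded=True``, and never count as significant.
    """

    taxon_id: str
    statistic: float
    p: float
    q: float
    direction: str
    significant: bool
    excluded: bool = False


_SCREEN_COLUMNS = ["taxon_id", "statistic", "p", "q", "direction", "significant"]


def write_screen_table(results: Sequence[ScreenResult], path: str | Path) -> None:
    """Write screen records as TSV, sorted by taxon id."""
    if not results:
        raise ValueError("cannot write an empty screen table")
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        fh.write("\t".join(_SCREEN_COLUMNS) + "\n")
        for r in sorted(results, key=lambda r: r.taxon_id):
            fh.write(
                f"{r.taxon_id}\t{format_float(r.statistic)}\t{format_float(r.p)}\t"
                f"{format_float(r.q)}\t{r.direction}\t{r.significant}\n"
            )


def read_screen_table(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype={"taxon_id": str})
    missing = [c for c in _SCREEN_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: missing columns {missing}")
    return df
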