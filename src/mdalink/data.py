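"""Core labeled-matrix containers and text I/O.

The whole pipeline works on three light containers: a binary
disease x microbe association matrix with ordered labels
(:class:`AssociationDataset`), labeled symmetric similarity matrices in
[0, 1] (:class:`SimilarityMatrix`), and a non-negative weight matrix for
the factorization loss (:class:`MaskMatrix`).  Files are plain TSV/CSV so
everything round-trips through pandas.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "AssociationDataset",
    "SimilarityMatrix",
    "MaskMatrix",
    "read_association_list",
    "write_association_list",
    "read_similarity_table",
    "write_similarity_table",
    "write_ranked_predictions",
    "default_mask",
    "sparsity_percent",
]

SIMILARITY_ROLES = ("symptom", "functional", "gip", "integrated")
MASK_SCHEMES = ("observed_positives", "all_ones", "custom_zero_weight")

# column names that mark an edge-list header row under header="auto"
_HEADER_TOKENS = {"disease", "diseases", "microbe", "microbes", "d", "m",
                  "disease_id", "microbe_id", "disease_name", "microbe_name"}


def _check_unique(labels: list[str], what: str) -> None:
    if len(set(labels)) != len(labels):
        seen, dups = set(), []
        for lab in labels:
            if lab in seen:
                dups.append(lab)
            seen.add(lab)
        raise ValueError(f"duplicate {what} labels: {sorted(set(dups))}")


@dataclass
class AssociationDataset:
    """Binary disease x microbe association matrix with ordered labels.

    ``X[i, j] == 1`` iff disease ``disease_labels[i]`` is associated with
    microbe ``microbe_labels[j]``.  A disease's interaction profile is its
    row of ``X``; a microbe's is its column.
    """

    disease_labels: list[str]
    microbe_labels: list[str]
    X: np.ndarray
    n_raw_pairs: int | None = None
    n_unique_pairs: int | None = None

    def __post_init__(self) -> None:
        self.X = np.asarray(self.X, dtype=float)
        self.disease_labels = list(self.disease_labels)
        self.microbe_labels = list(self.microbe_labels)
        _check_unique(self.disease_labels, "disease")
        _check_unique(self.microbe_labels, "microbe")
        nd, nm = self.X.shape
        if nd != len(self.disease_labels) or nm != len(self.microbe_labels):
            raise ValueError(
                f"matrix shape {self.X.shape} does not match label counts "
                f"({len(self.disease_labels)}, {len(self.microbe_labels)})"
            )
        if not np.isin(self.X, (0.0, 1.0)).all():
            raise ValueError("association matrix entries must be 0 or 1")

    @property
    def n_diseases(self) -> int:
        return self.X.shape[0]

    @property
    def n_microbes(self) -> int:
        return self.X.shape[1]

    @property
    def n_associations(self) -> int:
        return int(self.X.sum())

    def disease_profile(self, i: int) -> np.ndarray:
        """Interaction profile of disease *i* (row of X)."""
        return self.X[i, :]

    def microbe_profile(self, p: int) -> np.ndarray:
        """Interaction profile of microbe *p* (column of X)."""
        return self.X[:, p]

    def known_pairs(self) -> np.ndarray:
        """(n_associations, 2) array of (disease index, microbe index)."""
        return np.argwhere(self.X == 1)

    def with_masked(self, pairs: np.ndarray) -> "AssociationDataset":
        """Training copy with the given (i, j) positive pairs zeroed."""
        X = self.X.copy()
        pairs = np.atleast_2d(np.asarray(pairs, dtype=int))
        X[pairs[:, 0], pairs[:, 1]] = 0.0
        return AssociationDataset(self.disease_labels, self.microbe_labels, X)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.X, index=self.disease_labels,
                            columns=self.microbe_labels)


@dataclass
class SimilarityMatrix:
    """Labeled symmetric similarity matrix with entries in [0, 1]."""

    labels: list[str]
    S: np.ndarray
    role: str = "integrated"

    def __post_init__(self) -> None:
        self.S = np.asarray(self.S, dtype=float)
        self.labels = list(self.labels)
        if self.role not in SIMILARITY_ROLES:
            raise ValueError(f"unknown role {self.role!r}; expected one of {SIMILARITY_ROLES}")
        _check_unique(self.labels, "similarity")
        n = len(self.labels)
        if self.S.shape != (n, n):
            raise ValueError(f"similarity matrix shape {self.S.shape} != ({n}, {n})")
        if not np.isfinite(self.S).all():
            raise ValueError("similarity matrix contains non-finite entries")
        if np.abs(self.S - self.S.T).max(initial=0.0) > 1e-12:
            raise ValueError("similarity matrix is not symmetric (tol 1e-12)")
        if self.S.size and (self.S.min() < 0.0 or self.S.max() > 1.0):
            raise ValueError("similarity entries must lie in [0, 1]")
        if self.role == "gip" and not np.allclose(np.diag(self.S), 1.0, rtol=0, atol=0):
            raise ValueError("GIP similarity must have unit diagonal")

    @property
    def n(self) -> int:
        return len(self.labels)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.S, index=self.labels, columns=self.labels)


@dataclass
class MaskMatrix:
    """Non-negative weight matrix Y for the factorization loss.

    ``Y[i, j] == 0`` marks the cell as missing (excluded from the fit);
    positive weights scale its squared-error contribution.
    """

    Y: np.ndarray
    scheme: str = "observed_positives"

    def __post_init__(self) -> None:
        self.Y = np.asarray(self.Y, dtype=float)
        if (self.Y < 0).any():
            raise ValueError("mask entries must be non-negative")


def default_mask(dataset: AssociationDataset, scheme: str = "observed_positives",
                 w0: float | None = None) -> MaskMatrix:
    """Build the loss-weight matrix Y for a dataset.

    observed_positives
        Y = X: only observed associations carry loss; zeros are treated as
        missing (the default — database zeros are unverified, not negative).
    all_ones
        Y = 1 everywhere; the weighted factorization degenerates to
        standard NMF on the full matrix.
    custom_zero_weight
        Y = 1 where X = 1 and Y = ``w0`` in [0, 1) where X = 0.
    """
    if scheme == "observed_positives":
        return MaskMatrix(dataset.X.copy(), scheme)
    if scheme == "all_ones":
        return MaskMatrix(np.ones_like(dataset.X), scheme)
    if scheme == "custom_zero_weight":
        if w0 is None or not (0.0 <= w0 < 1.0):
            raise ValueError(f"custom_zero_weight requires w0 in [0, 1), got {w0!r}")
        Y = np.where(dataset.X == 1.0, 1.0, w0)
        return MaskMatrix(Y, scheme)
    raise ValueError(f"unknown mask scheme {scheme!r}; expected one of {MASK_SCHEMES}")


def sparsity_percent(dataset: AssociationDataset) -> float:
    """Percentage of disease-microbe cells with no observed association."""
    total = dataset.n_diseases * dataset.n_microbes
    return 100.0 * (1.0 - dataset.n_associations / total)


def _sniff_delimiter(first_line: str) -> str:
    if "\t" in first_line:
        return "\t"
    if "," in first_line:
        return ","
    return "\t"


def _looks_like_header(fields: list[str]) -> bool:
    return all(f.strip().lower() in _HEADER_TOKENS for f in fields[:2])


def read_association_list(path, dedupe: bool = True,
                          header: bool | str = "auto") -> AssociationDataset:
    """Read a two-column (disease, microbe) edge list into a binary matrix.

    Tab or comma delimited, auto-detected from the first line (tab is
    canonical).  Labels are whitespace-trimmed and compared
    case-sensitively; order of first appearance is preserved.  Duplicate
    pairs collapse to a single 1 when ``dedupe`` is on.  The raw and
    unique pair counts are recorded on the returned dataset.

    ``header`` may be True, False, or "auto" (first row skipped only if
    its fields look like column names such as "disease"/"microbe").
    """
    with open(path, "r", encoding="utf-8") as fh:
        lines = fh.read().splitlines()
    lines = [(ln_no, ln) for ln_no, ln in enumerate(lines, start=1) if ln.strip()]
    if not lines:
        raise ValueError(f"association file {path} is empty")

    delim = _sniff_delimiter(lines[0][1])
    rows: list[tuple[str, str]] = []
    for idx, (ln_no, ln) in enumerate(lines):
        fields = ln.split(delim)
        if len(fields) < 2:
            raise ValueError(f"line {ln_no}: expected >= 2 columns, got {len(fields)}")
        if idx == 0 and (header is True or (header == "auto" and _looks_like_header(fields))):
            continue
        d, m = fields[0].strip(), fields[1].strip()
        if not d or not m:
            raise ValueError(f"line {ln_no}: blank disease or microbe label")
        rows.append((d, m))
    if not rows:
        raise ValueError(f"association file {path} contains no data rows")

    n_raw = len(rows)
    seen: dict[tuple[str, str], None] = {}
    for pair in rows:
        if pair not in seen:
            seen[pair] = None
        elif not dedupe:
            raise ValueError(f"duplicate pair {pair} with dedupe disabled")
    unique_pairs = list(seen)

    diseases: dict[str, int] = {}
    microbes: dict[str, int] = {}
    for d, m in unique_pairs:
        diseases.setdefault(d, len(diseases))
        microbes.setdefault(m, len(microbes))
    X = np.zeros((len(diseases), len(microbes)))
    for d, m in unique_pairs:
        X[diseases[d], microbes[m]] = 1.0
    return AssociationDataset(
        list(diseases), list(microbes), X,
        n_raw_pairs=n_raw, n_unique_pairs=len(unique_pairs),
    )


def write_association_list(dataset: AssociationDataset, path,
                           header: bool = True) -> None:
    """Write the dataset's positive pairs as a two-column TSV edge list."""
    with open(path, "w", encoding="utf-8") as fh:
        if header:
            fh.write("disease\tmicrobe\n")
        for i, j in dataset.known_pairs():
            fh.write(f"{dataset.disease_labels[i]}\t{dataset.microbe_labels[j]}\n")


def read_similarity_table(path, expected_labels: list[str] | None = None,
                          role: str = "symptom") -> SimilarityMatrix:
    """Read a square labeled similarity table (TSV/CSV, one label column).

    Rows/columns are reordered to ``expected_labels`` when given (extra
    labels are dropped, missing ones raise).  Small asymmetries are fixed
    by averaging S with its transpose (warning above 1e-8); values outside
    [0, 1] are clipped with a warning.
    """
    df = pd.read_csv(path, sep=None, engine="python", index_col=0)
    df.index = df.index.astype(str).str.strip()
    df.columns = df.columns.astype(str).str.strip()
    if df.shape[0] != df.shape[1] or set(df.index) != set(df.columns):
        raise ValueError(
            f"similarity table {path} is not square-labeled: "
            f"{df.shape[0]} rows x {df.shape[1]} columns"
        )
    if expected_labels is not None:
        missing = [lab for lab in expected_labels if lab not in df.index]
        if missing:
            raise ValueError(f"similarity table missing labels: {missing}")
        df = df.loc[list(expected_labels), list(expected_labels)]
    try:
        S = df.to_numpy(dtype=float)
    except (TypeError, ValueError):
        bad = df.map(lambda v: not isinstance(v, (int, float, np.number)))
        r, c = np.argwhere(bad.to_numpy())[0]
        raise ValueError(
            f"non-numeric cell at row {df.index[r]!r}, column {df.columns[c]!r}"
        ) from None
    asym = np.abs(S - S.T).max(initial=0.0)
    if asym > 1e-8:
        warnings.warn(f"similarity table asymmetric (max deviation {asym:.3g}); "
                      "averaging with transpose", stacklevel=2)
    S = 0.5 * (S + S.T)
    if S.size and (S.min() < 0.0 or S.max() > 1.0):
        warnings.warn("similarity values outside [0, 1] clipped", stacklevel=2)
        S = np.clip(S, 0.0, 1.0)
    return SimilarityMatrix(list(df.index), S, role=role)


def write_similarity_table(sim: SimilarityMatrix, path) -> None:
    sim.to_frame().to_csv(path, sep="\t", index_label="label")


def write_ranked_predictions(scores: pd.DataFrame, dataset: AssociationDataset,
                             path, top_n: int | None = None) -> pd.DataFrame:
    """Write all (disease, microbe) scores ranked high-to-low as TSV.

    Columns: disease, microbe, score, rank, known_flag.  ``scores`` is a
    nd x nm DataFrame aligned with the dataset; ``top_n`` keeps the best N
    rows per disease.
    """
    long = scores.stack().rename("score").reset_index()
    long.columns = ["disease", "microbe", "score"]
    known = dataset.to_frame().stack().rename("known_flag").reset_index()
    known.columns = ["disease", "microbe", "known_flag"]
    long = long.merge(known, on=["disease", "microbe"])
    long["known_flag"] = long["known_flag"].astype(int)
    long = long.sort_values("score", ascending=False, kind="mergesort")
    long["rank"] = np.arange(1, len(long) + 1)
    if top_n is not None:
        long = (long.groupby("disease", group_keys=False, sort=False)
                    .head(top_n))
    long = long[["disease", "microbe", "score", "rank", "known_flag"]]
    long.to_csv(path, sep="\t", index=False)
    return long
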