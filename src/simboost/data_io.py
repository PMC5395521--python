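"""Affinity and similarity matrix containers, text I/O, and value transforms.

The binding-affinity matrix ``M`` (drugs x targets) is partially observed:
unobserved cells are NaN in ``values`` and False in ``observed``.  Similarity
matrices are square, symmetric, unit-diagonal and live in [0, 1] -- the
contract satisfied by Tanimoto/fingerprint similarities for compounds and
normalised Smith-Waterman scores for protein targets.

Matrices travel as delimited text: one header row of target ids, one leading
column of drug ids, tab- or comma-separated (auto-detected on load).
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field

import numpy as np

from .errors import DataFormatError

__all__ = [
    "AffinityMatrix",
    "SimilarityMatrix",
    "BinaryLabels",
    "load_affinity_matrix",
    "save_affinity_matrix",
    "load_similarity_matrix",
    "save_similarity_matrix",
    "kd_to_pkd",
    "kiba_transform",
    "binarize",
]

#: Tolerance for similarity-matrix symmetry / range violations attributable
#: to floating point noise in externally computed matrices.
SYMMETRY_TOL = 1e-8


@dataclass
class AffinityMatrix:
    """Partially observed drugs x targets matrix of continuous affinities.

    ``values[i, j]`` is the affinity of drug ``drug_ids[i]`` for target
    ``target_ids[j]`` (pK_d, pK_i or transformed KIBA score, larger = stronger
    binding); NaN where unobserved.  ``observed`` is the boolean mask of
    measured cells.
    """

    values: np.ndarray
    observed: np.ndarray
    drug_ids: list[str]
    target_ids: list[str]

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.observed = np.asarray(self.observed, dtype=bool)
        n_d, n_t = self.values.shape
        if n_d < 1 or n_t < 1:
            raise DataFormatError("affinity matrix must have >= 1 drug and >= 1 target")
        if self.observed.shape != self.values.shape:
            raise DataFormatError("observed mask shape does not match values")
        if len(self.drug_ids) != n_d or len(self.target_ids) != n_t:
            raise DataFormatError("id lists do not match matrix shape")
        if not np.all(np.isfinite(self.values[self.observed])):
            raise DataFormatError("observed cells must be finite")

    @property
    def n_drugs(self) -> int:
        return self.values.shape[0]

    @property
    def n_targets(self) -> int:
        return self.values.shape[1]

    @property
    def density(self) -> float:
        return float(self.observed.mean())

    def copy(self) -> "AffinityMatrix":
        return AffinityMatrix(
            self.values.copy(), self.observed.copy(),
            list(self.drug_ids), list(self.target_ids),
        )

    def drug_index(self, drug_id: str) -> int:
        try:
            return self.drug_ids.index(drug_id)
        except ValueError:
            raise KeyError(f"unknown drug id: {drug_id!r}") from None

    def target_index(self, target_id: str) -> int:
        try:
            return self.target_ids.index(target_id)
        except ValueError:
            raise KeyError(f"unknown target id: {target_id!r}") from None


@dataclass
class SimilarityMatrix:
    """Square symmetric similarity matrix in [0, 1] with unit diagonal."""

    values: np.ndarray
    ids: list[str]

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        n = len(self.ids)
        if self.values.shape != (n, n):
            raise DataFormatError("similarity matrix must be square and match ids")
        asym = np.abs(self.values - self.values.T).max() if n else 0.0
        if asym > SYMMETRY_TOL:
            raise DataFormatError(
                f"similarity matrix asymmetry {asym:.3g} exceeds tolerance {SYMMETRY_TOL}"
            )
        # symmetrize floating-point artifacts
        self.values = 0.5 * (self.values + self.values.T)
        if np.abs(np.diag(self.values) - 1.0).max() > SYMMETRY_TOL:
            raise DataFormatError("similarity diagonal must equal 1")
        np.fill_diagonal(self.values, 1.0)
        if self.values.min() < -SYMMETRY_TOL or self.values.max() > 1.0 + SYMMETRY_TOL:
            raise DataFormatError("similarity values must lie in [0, 1]")
        np.clip(self.values, 0.0, 1.0, out=self.values)

    @property
    def n(self) -> int:
        return len(self.ids)

    def row(self, entity_id: str) -> np.ndarray:
        return self.values[self.ids.index(entity_id)]


@dataclass
class BinaryLabels:
    """Binding / non-binding labels for the observed cells of an affinity matrix.

    ``labels`` is aligned with the affinity matrix; it is only meaningful where
    ``observed`` is True.
    """

    labels: np.ndarray
    observed: np.ndarray
    threshold: float
    direction: str  # ">=" (value above threshold binds) or "<=" (below binds)

    def observed_labels(self) -> np.ndarray:
        """Flat label vector over observed cells, row-major order."""
        return self.labels[self.observed]


def _sniff_delimiter(header_line: str) -> str:
    return "\t" if "\t" in header_line else ","


def load_affinity_matrix(path, missing_marker: str = "NA") -> AffinityMatrix:
    """Load a drugs x targets affinity matrix from delimited text.

    The first row holds target ids (first field is an ignored corner label),
    the first column holds drug ids.  Cells equal to ``missing_marker`` become
    unobserved.
    """
    with open(path, newline="") as fh:
        first = fh.readline()
        if not first.strip():
            raise DataFormatError(f"{path}: empty file")
        delim = _sniff_delimiter(first)
        header = next(csv.reader([first], delimiter=delim))
        target_ids = [h.strip() for h in header[1:]]
        if not target_ids:
            raise DataFormatError(f"{path}: header row has no target ids")
        drug_ids: list[str] = []
        rows: list[list[float]] = []
        masks: list[list[bool]] = []
        for lineno, rec in enumerate(csv.reader(fh, delimiter=delim), start=2):
            if not rec:
                continue
            if len(rec) != len(target_ids) + 1:
                raise DataFormatError(
                    f"{path}:{lineno}: expected {len(target_ids) + 1} fields, got {len(rec)}"
                )
            drug_ids.append(rec[0].strip())
            vals, mask = [], []
            for j, cell in enumerate(rec[1:]):
                cell = cell.strip()
                if cell == missing_marker:
                    vals.append(np.nan)
                    mask.append(False)
                else:
                    try:
                        vals.append(float(cell))
                    except ValueError:
                        raise DataFormatError(
                            f"{path}:{lineno}: non-numeric cell {cell!r} at "
                            f"drug {rec[0]!r}, target {target_ids[j]!r}"
                        ) from None
                    mask.append(True)
            rows.append(vals)
            masks.append(mask)
    if not rows:
        raise DataFormatError(f"{path}: no data rows")
    return AffinityMatrix(np.array(rows), np.array(masks), drug_ids, target_ids)


def save_affinity_matrix(m: AffinityMatrix, path, missing_marker: str = "NA",
                         delimiter: str = "\t") -> None:
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh, delimiter=delimiter)
        w.writerow(["id"] + m.target_ids)
        for i, did in enumerate(m.drug_ids):
            row = [
                repr(float(m.values[i, j])) if m.observed[i, j] else missing_marker
                for j in range(m.n_targets)
            ]
            w.writerow([did] + row)


def load_similarity_matrix(path) -> SimilarityMatrix:
    """Load a square similarity matrix; symmetry/range validated on construction."""
    with open(path, newline="") as fh:
        first = fh.readline()
        if not first.strip():
            raise DataFormatError(f"{path}: empty file")
        delim = _sniff_delimiter(first)
        header = next(csv.reader([first], delimiter=delim))
        ids = [h.strip() for h in header[1:]]
        rows = []
        row_ids = []
        for lineno, rec in enumerate(csv.reader(fh, delimiter=delim), start=2):
            if not rec:
                continue
            if len(rec) != len(ids) + 1:
                raise DataFormatError(
                    f"{path}:{lineno}: expected {len(ids) + 1} fields, got {len(rec)}"
                )
            row_ids.append(rec[0].strip())
            try:
                rows.append([float(c) for c in rec[1:]])
            except ValueError as exc:
                raise DataFormatError(f"{path}:{lineno}: {exc}") from None
    if row_ids != ids:
        raise DataFormatError(f"{path}: row ids do not match header ids")
    return SimilarityMatrix(np.array(rows), ids)


def save_similarity_matrix(s: SimilarityMatrix, path, delimiter: str = "\t") -> None:
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh, delimiter=delimiter)
        w.writerow(["id"] + s.ids)
        for i, eid in enumerate(s.ids):
            w.writerow([eid] + [repr(float(v)) for v in s.values[i]])


def kd_to_pkd(kd):
    """Log-transform dissociation constants (nM) to pK_d = -log10(K_d / 1e9).

    A K_d of 10,000 nM (the 'no binding detected' ceiling in selectivity
    assays) maps to pK_d = 5.
    """
    kd = np.asarray(kd, dtype=float)
    if np.any(kd[np.isfinite(kd)] <= 0):
        raise ValueError("K_d values must be positive")
    out = -np.log10(kd / 1e9)
    return float(out) if out.ndim == 0 else out


def kiba_transform(m: AffinityMatrix, shift: float | None = None) -> AffinityMatrix:
    """Negate-and-shift KIBA scores so larger output means stronger binding.

    Each observed value v becomes ``-v + shift``; the default shift is the
    maximum observed value, so the transformed minimum is exactly 0 and the
    binarization cutoff KIBA <= 3.0 becomes a '>= 12.1'-style threshold on the
    transformed scale.  Pass the recorded shift back in to invert (the
    transform is an involution for fixed shift).
    """
    if not m.observed.any():
        raise DataFormatError("kiba_transform requires at least one observed value")
    if shift is None:
        shift = float(np.nanmax(m.values[m.observed]))
    out = m.copy()
    out.values[out.observed] = -out.values[out.observed] + shift
    return out


def binarize(m: AffinityMatrix, threshold: float, direction: str = ">=") -> BinaryLabels:
    """Threshold observed affinities into binding (True) / non-binding labels.

    ``direction=">="`` labels values at or above the threshold as binding
    (log-scale affinities); ``"<="`` labels values at or below (raw KIBA
    scores).  The threshold itself is binding under both directions.
    Unobserved cells stay unlabeled.
    """
    if not np.isfinite(threshold):
        raise ValueError("threshold must be finite")
    if direction not in (">=", "<="):
        raise ValueError("direction must be '>=' or '<='")
    labels = np.zeros_like(m.observed, dtype=bool)
    with np.errstate(invalid="ignore"):
        if direction == ">=":
            cmp = m.values >= threshold
        else:
            cmp = m.values <= threshold
    labels[m.observed] = cmp[m.observed]
    return BinaryLabels(labels, m.observed.copy(), float(threshold), direction)
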