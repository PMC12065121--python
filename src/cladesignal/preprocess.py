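"""Curation and one-hot encoding of terminal-level host/biogeography metadata.

The metadata table holds one row per tree terminal with categorical
features describing the host taxonomy (class, order, family, genus,
species), ecology (habitat; aquatic-ecosystem type) and biogeography
(zoogeographical region, continent, country/river basin).  Curation
filters it down to rows usable for supervised clade prediction; encoding
expands the survivors into a binary design matrix.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, asdict
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, TransformerMixin
from sklearn.utils.validation import check_is_fitted

from .errors import CurationError, ValidationError

#: Canonical feature columns, in analysis order.
DEFAULT_FEATURES = (
    "CatHC",  # host class
    "CatHO",  # host order
    "CatHF",  # host family
    "CatHG",  # host genus
    "CatHS",  # host species
    "CatE1",  # habitat (aquatic / terrestrial)
    "CatE2",  # aquatic ecosystem (fresh / brackish / salt water)
    "CatL1",  # zoogeographical region (realm)
    "CatL2",  # continent
    "CatL5",  # country or river basin
)

ROLE_COLUMN = "host_role"
#: Host roles excluded from the analysis table.
EXCLUDED_ROLES = frozenset({"intermediate", "paratenic"})

_MISSING_TOKENS = {"", "?", "nan", "NaN"}


def _is_missing(series: pd.Series) -> pd.Series:
    return series.isna() | series.astype(str).isin(_MISSING_TOKENS)


@dataclass
class CurationReport:
    """Row/column counts dropped at each curation step."""

    n_input: int
    dropped_role: int
    dropped_columns: list[str]
    dropped_missing: int
    dropped_unlabelled: int
    n_output: int

    def to_json(self, path=None) -> str:
        text = json.dumps(asdict(self), indent=1)
        if path is not None:
            with open(path, "w", encoding="utf-8") as fh:
                fh.write(text + "\n")
        return text


def curate(
    raw: pd.DataFrame,
    features: Sequence[str] = DEFAULT_FEATURES,
    labels: Mapping[str, str] | None = None,
    *,
    role_column: str = ROLE_COLUMN,
    column_missing_threshold: float = 1.0,
    synonym_map: Mapping[str, str] | None = None,
) -> tuple[pd.DataFrame, CurationReport]:
    """Filter a raw metadata table down to the analysis-ready subset.

    Steps, in order: (1) drop intermediate/paratenic-host rows; (2) restrict
    to the requested features; (3) drop feature columns whose missingness
    exceeds ``column_missing_threshold`` (default 1.0: only fully-missing
    columns go); (4) drop rows with any remaining missing cell; (5) drop
    rows without a clade label.  An optional ``synonym_map`` (value ->
    canonical value) is applied before anything else.

    Returns the curated table and a :class:`CurationReport`.
    """
    missing_cols = [f for f in features if f not in raw.columns]
    if missing_cols:
        raise ValidationError(
            f"requested features absent from table: {missing_cols}"
        )
    table = raw.copy()
    if synonym_map:
        table[list(features)] = table[list(features)].replace(synonym_map)

    n_input = len(table)
    # 1. host-role filter
    if role_column in table.columns:
        roles = table[role_column].astype(str).str.lower()
        table = table.loc[~roles.isin(EXCLUDED_ROLES)]
    dropped_role = n_input - len(table)
    if table.empty:
        raise CurationError("no rows left after host-role filtering")

    # 2. feature restriction
    table = table[list(features)]

    # 3. column missingness filter
    frac_missing = table.apply(_is_missing).mean()
    dropped_columns = [
        c for c in table.columns if frac_missing[c] > column_missing_threshold
        or frac_missing[c] == 1.0
    ]
    table = table.drop(columns=dropped_columns)
    if table.shape[1] == 0:
        raise CurationError("no feature columns left after missingness filter")

    # 4. row missingness filter
    before = len(table)
    table = table.loc[~table.apply(_is_missing).any(axis=1)]
    dropped_missing = before - len(table)
    if table.empty:
        raise CurationError("no rows left after missing-data removal")

    # 5. label filter
    before = len(table)
    if labels is not None:
        table = table.loc[table.index.isin(set(labels))]
    dropped_unlabelled = before - len(table)
    if table.empty:
        raise CurationError("no rows left after clade-label filtering")

    report = CurationReport(
        n_input=n_input,
        dropped_role=dropped_role,
        dropped_columns=dropped_columns,
        dropped_missing=dropped_missing,
        dropped_unlabelled=dropped_unlabelled,
        n_output=len(table),
    )
    return table.astype(str), report


def check_hierarchy(
    table: pd.DataFrame, nesting: Mapping[str, str]
) -> list[str]:
    """Warn about child categories mapped to multiple parent categories.

    ``nesting`` maps child column -> parent column (e.g. species -> genus).
    Violations are reported as warnings and returned; nothing is corrected.
    """
    problems = []
    for child, parent in nesting.items():
        if child not in table.columns or parent not in table.columns:
            continue
        parents_per_value = table.groupby(child)[parent].nunique()
        for value in parents_per_value[parents_per_value > 1].index:
            msg = f"{child}={value!r} maps to multiple {parent} values"
            problems.append(msg)
            warnings.warn(msg, stacklevel=2)
    return problems


class CladeOneHotEncoder(BaseEstimator, TransformerMixin):
    """One-hot expansion of a curated categorical table.

    One binary column per observed (feature, value) pair, named
    ``"feature=value"``; columns are ordered by feature and, within a
    feature, by first observation in the fitting table.  The mapping is
    persisted (``to_json``/``from_json``) so new rows encode identically.
    The expansion is lossless: :meth:`inverse_transform` reproduces the
    curated table exactly.
    """

    def fit(self, X: pd.DataFrame, y=None):
        self._check_no_missing(X)
        self.feature_names_in_ = np.asarray(X.columns, dtype=object)
        self.categories_ = {
            col: list(pd.unique(X[col].astype(str))) for col in X.columns
        }
        self.columns_ = [
            f"{col}={val}"
            for col in X.columns
            for val in self.categories_[col]
        ]
        return self

    @staticmethod
    def _check_no_missing(X: pd.DataFrame) -> None:
        bad = X.apply(_is_missing).any(axis=1)
        if bad.any():
            raise ValidationError(
                "missing cells in table passed to the encoder "
                f"(curation contract breached): rows {list(X.index[bad])[:5]}"
            )

    def transform(self, X: pd.DataFrame) -> pd.DataFrame:
        check_is_fitted(self, "categories_")
        self._check_no_missing(X)
        blocks = {}
        for col, cats in self.categories_.items():
            observed = X[col].astype(str)
            unknown = set(observed) - set(cats)
            if unknown:
                raise ValidationError(
                    f"feature {col!r}: unseen categories {sorted(unknown)}"
                )
            for val in cats:
                blocks[f"{col}={val}"] = (
                    (observed == val).to_numpy(dtype=np.uint8)
                )
        return pd.DataFrame(blocks, index=X.index)[self.columns_]

    def inverse_transform(self, X: pd.DataFrame) -> pd.DataFrame:
        check_is_fitted(self, "categories_")
        decoded = {}
        for col, cats in self.categories_.items():
            block = X[[f"{col}={val}" for val in cats]].to_numpy()
            if not (block.sum(axis=1) == 1).all():
                raise ValidationError(
                    f"feature {col!r}: rows without exactly one active column"
                )
            decoded[col] = [cats[i] for i in block.argmax(axis=1)]
        return pd.DataFrame(decoded, index=X.index)

    def get_feature_names_out(self, input_features=None):
        check_is_fitted(self, "columns_")
        return np.asarray(self.columns_, dtype=object)

    # -- persistence -------------------------------------------------------

    def to_json(self, path=None) -> str:
        check_is_fitted(self, "categories_")
        text = json.dumps(self.categories_, indent=1)
        if path is not None:
            with open(path, "w", encoding="utf-8") as fh:
                fh.write(text + "\n")
        return text

    @classmethod
    def from_json(cls, source) -> "CladeOneHotEncoder":
        if hasattr(source, "read"):
            categories = json.load(source)
        else:
            try:
                categories = json.loads(source)
            except (json.JSONDecodeError, TypeError):
                with open(source, encoding="utf-8") as fh:
                    categories = json.load(fh)
        enc = cls()
        enc.feature_names_in_ = np.asarray(list(categories), dtype=object)
        enc.categories_ = {k: list(v) for k, v in categories.items()}
        enc.columns_ = [
            f"{col}={val}" for col in categories for val in categories[col]
        ]
        return enc


def one_hot(
    table: pd.DataFrame, labels: Mapping[str, str] | None = None
) -> tuple[pd.DataFrame, pd.Series | None, CladeOneHotEncoder]:
    """Encode a curated table; convenience wrapper over the estimator.

    Returns ``(encoded, aligned_labels, fitted_encoder)``.
    """
    encoder = CladeOneHotEncoder().fit(table)
    encoded = encoder.transform(table)
    aligned = None
    if labels is not None:
        aligned = pd.Series(
            [labels[t] for t in table.index], index=table.index, name="clade"
        )
    return encoded, aligned, encoder


def summarize(table: pd.DataFrame) -> dict:
    """Row, feature, data-point and per-feature cardinality counts."""
    cards = {col: int(table[col].nunique()) for col in table.columns}
    return {
        "rows": int(len(table)),
        "features": int(table.shape[1]),
        "data_points": int(len(table) * table.shape[1]),
        "cardinalities": cards,
        "encoded_width": int(sum(cards.values())),
    }
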