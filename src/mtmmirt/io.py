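"""Reading and writing responses, designs, draws and fit reports.

Response files are CSV, either *long* (canonical; columns
``person_id,item_id,response``) or *wide* (one column per item plus a
``person_id`` column).  Observed responses must be strictly binary —
polytomous inventories are dichotomized upstream (e.g. the verbal
aggression data combines Perhaps with Yes); anything else is a parse
error naming the offending row.

Fit reports are written as JSON (machine-readable, round-trips
bit-for-bit) together with human-readable tables: a parameter table
laid out item-by-item with the intercept, the method (situation)
loading and the trait (behavior) loading plus the trait correlations,
and a coefficient table with the per-item method-specificity and
consistency shares.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd

from .design import MTMMDesign
from .model import (CoefficientTable, ModelParameters, ResponseMatrix,
                    validity_coefficients)
from .results import FitResult

__all__ = ["ResponseParseError", "read_responses", "write_responses",
           "read_loadings", "write_fit", "read_fit",
           "format_parameter_table", "format_coefficient_table",
           "write_draws_csv", "read_draws_csv"]


class ResponseParseError(ValueError):
    """Raised for malformed response files."""


def _coerce_response(value, where: str) -> float:
    if pd.isna(value) or value == "":
        return np.nan
    try:
        v = float(value)
    except (TypeError, ValueError):
        raise ResponseParseError(
            f"non-numeric response {value!r} at {where}") from None
    if v not in (0.0, 1.0):
        raise ResponseParseError(
            f"non-binary response {value!r} at {where}; responses must be "
            "dichotomized upstream (e.g. collapse Perhaps with Yes to 1)")
    return v


def read_responses(path: str | Path, format: str = "long",
                   design: Optional[MTMMDesign] = None) -> ResponseMatrix:
    """Read a response CSV into a person-by-item matrix.

    With a ``design``, items are aligned to the design's item order and
    unknown item labels are an error; without one, item order follows
    first appearance (long) or column order (wide).
    """
    path = Path(path)
    df = pd.read_csv(path, dtype=str)
    if df.empty:
        raise ResponseParseError(f"response file {path} is empty")
    if format == "long":
        required = {"person_id", "item_id", "response"}
        if not required.issubset(df.columns):
            raise ResponseParseError(
                f"long format requires columns {sorted(required)}")
        if df.duplicated(["person_id", "item_id"]).any():
            dup = df[df.duplicated(["person_id", "item_id"])].iloc[0]
            raise ResponseParseError(
                f"duplicate person-item pair ({dup['person_id']}, {dup['item_id']})")
        items = (list(design.item_labels) if design is not None
                 else list(dict.fromkeys(df["item_id"])))
        unknown = set(df["item_id"]) - set(items)
        if unknown:
            raise ResponseParseError(f"unknown item labels {sorted(unknown)}")
        persons = list(dict.fromkeys(df["person_id"]))
        y = np.full((len(persons), len(items)), np.nan)
        p_idx = {p: k for k, p in enumerate(persons)}
        i_idx = {i: k for k, i in enumerate(items)}
        for row in df.itertuples(index=False):
            v = _coerce_response(row.response,
                                 f"(person {row.person_id}, item {row.item_id})")
            y[p_idx[row.person_id], i_idx[row.item_id]] = v
        return ResponseMatrix(y, tuple(persons))
    if format == "wide":
        cols = [c for c in df.columns if c != "person_id"]
        if design is not None:
            unknown = set(cols) - set(design.item_labels)
            if unknown:
                raise ResponseParseError(f"unknown item columns {sorted(unknown)}")
            cols = [c for c in design.item_labels if c in cols]
            if len(cols) != design.n_items:
                missing = set(design.item_labels) - set(cols)
                raise ResponseParseError(f"missing item columns {sorted(missing)}")
        persons = (df["person_id"].tolist() if "person_id" in df.columns
                   else [f"p{k + 1}" for k in range(len(df))])
        y = np.full((len(df), len(cols)), np.nan)
        for j, c in enumerate(cols):
            for k, value in enumerate(df[c]):
                y[k, j] = _coerce_response(value, f"(row {k + 1}, item {c})")
        return ResponseMatrix(y, tuple(persons))
    raise ValueError(f"unknown format {format!r}; expected 'long' or 'wide'")


def write_responses(data: ResponseMatrix, design: MTMMDesign,
                    path: str | Path, format: str = "long") -> None:
    path = Path(path)
    if format == "long":
        rows = []
        for p, pid in enumerate(data.person_ids):
            for i, lab in enumerate(design.item_labels):
                v = data.responses[p, i]
                if not np.isnan(v):
                    rows.append((pid, lab, int(v)))
        pd.DataFrame(rows, columns=["person_id", "item_id", "response"]).to_csv(
            path, index=False)
    elif format == "wide":
        df = pd.DataFrame(data.responses, columns=list(design.item_labels))
        df = df.astype("Int64")
        df.insert(0, "person_id", list(data.person_ids))
        df.to_csv(path, index=False)
    else:
        raise ValueError(f"unknown format {format!r}")


def read_loadings(path: str | Path, design: MTMMDesign):
    """CSV with columns ``item,trait_loading,method_loading`` (any order
    of rows); returns the two loading vectors in design item order."""
    df = pd.read_csv(Path(path))
    required = {"item", "trait_loading", "method_loading"}
    if not required.issubset(df.columns):
        raise ValueError(f"loadings file requires columns {sorted(required)}")
    df = df.set_index("item")
    missing = set(design.item_labels) - set(df.index.astype(str))
    if missing:
        raise ValueError(f"loadings missing for items {sorted(missing)}")
    df.index = df.index.astype(str)
    tl = df.loc[list(design.item_labels), "trait_loading"].to_numpy(dtype=float)
    ml = df.loc[list(design.item_labels), "method_loading"].to_numpy(dtype=float)
    return tl, ml


# ---------------------------------------------------------------------------
# Fit reports


def format_parameter_table(design: MTMMDesign, params: ModelParameters) -> pd.DataFrame:
    """Item-by-column table: intercept, one column per method factor
    (the item's method loading in its own method's column), one column
    per trait factor; trait correlations appended as extra rows."""
    rows = {}
    for i, lab in enumerate(design.item_labels):
        row = {"Intercept": params.intercepts[i]}
        for m, mlab in enumerate(design.method_labels):
            row[mlab] = (params.method_loadings[i]
                         if design.method_of_item[i] == m else np.nan)
        for t, tlab in enumerate(design.trait_labels):
            row[tlab] = (params.trait_loadings[i]
                         if design.trait_of_item[i] == t else np.nan)
        rows[lab] = row
    df = pd.DataFrame(rows).T
    for a in range(design.n_traits):
        for b in range(a + 1, design.n_traits):
            name = f"Cor({design.trait_labels[a]},{design.trait_labels[b]})"
            row = {c: np.nan for c in df.columns}
            row["Intercept"] = params.trait_correlation[a, b]
            df.loc[name] = row
    return df


def format_coefficient_table(design: MTMMDesign,
                             table: CoefficientTable) -> pd.DataFrame:
    """Method-specificity and consistency coefficients in the same
    item-by-factor layout as the parameter table."""
    rows = {}
    for i, lab in enumerate(design.item_labels):
        row = {}
        for m, mlab in enumerate(design.method_labels):
            row[mlab] = (table.method_specificity[i]
                         if design.method_of_item[i] == m else np.nan)
        for t, tlab in enumerate(design.trait_labels):
            row[tlab] = (table.consistency[i]
                         if design.trait_of_item[i] == t else np.nan)
        rows[lab] = row
    return pd.DataFrame(rows).T


def write_fit(result: FitResult, design: MTMMDesign, path: str | Path,
              convention: str = "squared") -> dict:
    """Serialize a fit: JSON at ``path`` plus a plain-text report at
    ``path`` with suffix ``.txt``.  Returns the JSON payload."""
    path = Path(path)
    p = result.estimates
    payload = {
        "estimator": result.estimator_tag,
        "seed": result.seed,
        "converged": bool(result.converged),
        "n_iterations": int(result.n_iterations),
        "log_likelihood": result.log_likelihood,
        "link": p.link,
        "design": {"items": design.to_items()},
        "estimates": {
            "trait_loadings": p.trait_loadings.tolist(),
            "method_loadings": p.method_loadings.tolist(),
            "intercepts": p.intercepts.tolist(),
            "trait_correlation": p.trait_correlation.tolist(),
        },
        "diagnostics": {k: (None if v is None else float(v))
                        for k, v in result.diagnostics.items()},
    }
    path.write_text(json.dumps(payload, indent=2))
    coef = validity_coefficients(p, convention=convention)
    txt = [
        f"estimator: {result.estimator_tag}   seed: {result.seed}   "
        f"converged: {result.converged}",
        f"objective: {result.log_likelihood:.4f}",
        "",
        "Parameter estimates",
        format_parameter_table(design, p).to_string(float_format="%.3f",
                                                    na_rep=""),
        "",
        f"Validity coefficients ({coef.convention} convention)",
        format_coefficient_table(design, coef).to_string(float_format="%.3f",
                                                         na_rep=""),
    ]
    path.with_suffix(".txt").write_text("\n".join(txt) + "\n")
    return payload


def read_fit(path: str | Path, link: Optional[str] = None) -> FitResult:
    """Round-trip a JSON fit report back into a FitResult."""
    payload = json.loads(Path(path).read_text())
    est = payload["estimates"]
    params = ModelParameters(
        np.array(est["trait_loadings"]),
        np.array(est["method_loadings"]),
        np.array(est["intercepts"]),
        np.array(est["trait_correlation"]),
        link=link or payload.get("link", "logit"),
    )
    return FitResult(
        estimates=params,
        log_likelihood=payload["log_likelihood"],
        converged=payload["converged"],
        n_iterations=payload["n_iterations"],
        estimator_tag=payload["estimator"],
        seed=payload.get("seed"),
        diagnostics=payload.get("diagnostics", {}),
    )


# ---------------------------------------------------------------------------
# Posterior draws


def write_draws_csv(samples, path: str | Path) -> None:
    samples.to_frame().to_csv(Path(path), index=False)


def read_draws_csv(path: str | Path, prior=None):
    """Read posterior draws (one column per parameter, ``chain`` column)."""
    from .mcll import PosteriorSamples, PriorSpec
    df = pd.read_csv(Path(path))
    if "chain" not in df.columns:
        raise ValueError("draws file must contain a 'chain' column")
    chains = df.pop("chain").to_numpy(dtype=int)
    return PosteriorSamples(df.to_numpy(dtype=float), chains,
                            list(df.columns), prior or PriorSpec(),
                            meta={"source": str(path)})
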