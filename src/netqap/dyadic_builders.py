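"""Pseudo-network transformation: node attributes to dyadic covariates.

Network regression needs every variable at the dyad level, so individual
attributes are re-expressed as square matrices over ordered pupil pairs:

* categorical / binary attributes (class, gender, ethnicity) become
  **match** matrices — cell (i, j) = 1 iff both pupils share the category;
* numeric attributes (parent age, Likert relevance scores, medical-visit
  category) become **absolute-difference** matrices — the smaller the
  difference, the more similar (homophilous) the dyad.

The binary response (new vaccination within a month of the intervention)
becomes an outcome-similarity matrix: cell (i, j) = 1 iff pupils i and j
reacted the same way. For a binary vector this coincides with its match
matrix, an identity the test-suite uses as an oracle.

``build_design`` assembles the full regression design for the three model
presets: school network + mechanisms + controls (``model1``), the
after-school analogue (``model2``), and controls only (``model3``).
Covariate names are frozen to the published row labels so reports remain
comparable across studies.
"""

from __future__ import annotations

from collections.abc import Mapping, Sequence

import numpy as np
import pandas as pd

from . import structural_effects as se
from .net_model import (
    DyadDesign,
    DyadicMatrix,
    Network,
    NodeTable,
    ValidationError,
    dyad_index,
    vectorize,
)

__all__ = [
    "match_matrix",
    "absdiff_matrix",
    "outcome_similarity_matrix",
    "build_design",
    "dyadic_covariates",
    "CONTROL_COVARIATES",
    "NETWORK_LABELS",
    "MECHANISM_SUFFIXES",
    "MODEL_PRESETS",
    "RESPONSE_LABEL",
]

RESPONSE_LABEL = "Positive Responsiveness"

#: Frozen control-covariate labels -> (node attribute, transform).
CONTROL_COVARIATES: dict[str, tuple[str, str]] = {
    "Pupils' Ethnicity": ("ethnicity", "match"),
    "Pupils' Attending Class": ("class_label", "match"),
    "Pupils' Gender": ("gender", "match"),
    "Pupils' Perceived Relevance of Vaccination": ("pupil_relevance", "absdiff"),
    "Parents' Perceived Relevance of Vaccination": ("parent_relevance", "absdiff"),
    "Parent's Age": ("parent_age", "absdiff"),
    "Pupils' Medical Visits": ("medical_visits", "absdiff"),
}

NETWORK_LABELS: dict[str, str] = {
    "school": "School Friendship Network",
    "after_school": "After-School Friendship Network",
}

#: Mechanism-term suffixes appended to a network label.
MECHANISM_SUFFIXES = ("Reciprocity", "Closure", "Preferential Attachment")


def _network_terms(context: str) -> list[str]:
    base = NETWORK_LABELS[context]
    return [base] + [f"{base}—{suffix}" for suffix in MECHANISM_SUFFIXES]


#: The three published model specifications.
MODEL_PRESETS: dict[str, tuple[str, ...]] = {
    "model1": tuple(_network_terms("school") + list(CONTROL_COVARIATES)),
    "model2": tuple(_network_terms("after_school") + list(CONTROL_COVARIATES)),
    "model3": tuple(CONTROL_COVARIATES),
}


def _check_no_missing(values: np.ndarray, node_ids: Sequence[str] | None) -> None:
    na = pd.isna(values)
    if na.any():
        pos = int(np.nonzero(na)[0][0])
        who = node_ids[pos] if node_ids is not None else f"position {pos}"
        raise ValidationError(f"missing attribute value for node {who}")


def match_matrix(
    attr: Sequence, label: str, node_ids: Sequence[str] | None = None
) -> DyadicMatrix:
    """Binary similarity matrix: cell (i, j) = 1 iff attr(i) == attr(j), i != j."""
    values = np.asarray(attr, dtype=object)
    _check_no_missing(values, node_ids)
    eq = (values[:, None] == values[None, :]).astype(float)
    return DyadicMatrix(values=eq, label=label, symmetric=True)


def absdiff_matrix(
    attr: Sequence, label: str, node_ids: Sequence[str] | None = None
) -> DyadicMatrix:
    """Dissimilarity matrix: cell (i, j) = |attr(i) - attr(j)|."""
    raw = np.asarray(attr)
    _check_no_missing(raw, node_ids)
    try:
        values = raw.astype(float)
    except (TypeError, ValueError) as exc:
        raise ValidationError(f"attribute for {label!r} is not numeric") from exc
    diff = np.abs(values[:, None] - values[None, :])
    return DyadicMatrix(values=diff, label=label, symmetric=True)


def outcome_similarity_matrix(
    response: Sequence, node_ids: Sequence[str] | None = None
) -> DyadicMatrix:
    """Response matrix: cell (i, j) = 1 iff pupils i and j reacted the same way."""
    values = np.asarray(response, dtype=float)
    _check_no_missing(values, node_ids)
    if not np.isin(values, [0, 1]).all():
        raise ValidationError("positive_response values must be binary 0/1")
    sim = (values[:, None] == values[None, :]).astype(float)
    return DyadicMatrix(values=sim, label=RESPONSE_LABEL, symmetric=True)


# ---------------------------------------------------------------------------
# design assembly
# ---------------------------------------------------------------------------


def _control_matrix(name: str, table: NodeTable, standardize: bool) -> DyadicMatrix:
    attr, transform = CONTROL_COVARIATES[name]
    values = table.attribute(attr)
    if transform == "match":
        return match_matrix(values, name, table.node_ids)
    mat = absdiff_matrix(values, name, table.node_ids)
    if standardize:
        vec = mat.vector()
        sd = vec.std()
        if sd > 0:
            mat = DyadicMatrix(
                values=(mat.values - vec.mean()) / sd, label=name, symmetric=False
            )
    return mat


def _mechanism_matrix(
    name: str, network: Network, modes: se.StructuralModes
) -> DyadicMatrix:
    if name.endswith("Reciprocity"):
        return se.reciprocity_matrix(network, label=name)
    if name.endswith("Closure"):
        return se.closure_matrix(network, mode=modes.closure, label=name)
    return se.preferential_attachment_matrix(network, mode=modes.attachment, label=name)


def dyadic_covariates(
    node_table: NodeTable,
    networks: Mapping[str, Network],
    names: Sequence[str],
    modes: se.StructuralModes | None = None,
    standardize: bool = False,
) -> dict[str, DyadicMatrix]:
    """Resolve covariate names to dyadic matrices, in the order requested."""
    modes = modes or se.StructuralModes()
    label_to_context = {label: ctx for ctx, label in NETWORK_LABELS.items()}
    out: dict[str, DyadicMatrix] = {}
    for name in names:
        if name in CONTROL_COVARIATES:
            out[name] = _control_matrix(name, node_table, standardize)
            continue
        base = name.split("—")[0]
        if base in label_to_context:
            context = label_to_context[base]
            if context not in networks:
                raise ValidationError(
                    f"covariate {name!r} needs the {context!r} network, which was not supplied"
                )
            network = networks[context]
            if network.nodes != node_table.node_ids:
                raise ValidationError(
                    f"{context} network node order differs from the node table"
                )
            if name == base:
                out[name] = network.as_dyadic(label=name)
            else:
                out[name] = _mechanism_matrix(name, network, modes)
            continue
        valid = list(CONTROL_COVARIATES) + [
            t for ctx in NETWORK_LABELS for t in _network_terms(ctx)
        ]
        raise ValidationError(
            f"unknown covariate {name!r}; valid names: {', '.join(valid)}"
        )
    return out


def build_design(
    node_table: NodeTable,
    networks: Mapping[str, Network],
    model_spec: str | Sequence[str] = "model2",
    modes: se.StructuralModes | None = None,
    standardize: bool = False,
) -> DyadDesign:
    """Assemble the ordered-dyad regression design for one model.

    ``model_spec`` is a preset name (``model1``/``model2``/``model3``) or an
    explicit covariate-name sequence. The response is the vectorized
    outcome-similarity matrix; predictors are vectorized in spec order.
    """
    if isinstance(model_spec, str):
        if model_spec not in MODEL_PRESETS:
            raise ValidationError(
                f"unknown model preset {model_spec!r}; valid: {', '.join(MODEL_PRESETS)}"
            )
        names: Sequence[str] = MODEL_PRESETS[model_spec]
    else:
        names = list(model_spec)

    for network in networks.values():
        if network.nodes != node_table.node_ids:
            raise ValidationError(
                f"{network.context} network node order differs from the node table"
            )

    response = outcome_similarity_matrix(node_table.outcome(), node_table.node_ids)
    matrices = dyadic_covariates(node_table, networks, names, modes, standardize)
    n = node_table.n
    return DyadDesign(
        response=vectorize(response),
        predictors={name: vectorize(matrices[name]) for name in names},
        dyad_index=dyad_index(n),
        node_ids=node_table.node_ids,
    )
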