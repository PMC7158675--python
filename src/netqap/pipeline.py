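"""Full-study orchestration: QAP correlation matrix and the three LRQAP models.

Mirrors the reporting conventions of school-cohort network studies: a
lower-triangular correlation table over all sixteen dyadic variables
(outcome similarity, each friendship network with its three social
mechanisms, and the seven attribute controls) with significance stars, and
a three-column model table (school-network model, after-school model,
controls-only model) printing each coefficient with its odds ratio in
parentheses and stars, plus footer rows for the number of ordered dyads,
the permutation count, the model p-value and the fit statistic.
"""

from __future__ import annotations

import hashlib
import json
import os
from collections.abc import Mapping, Sequence
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import __version__ as _version
from .dyadic_builders import (
    CONTROL_COVARIATES,
    MODEL_PRESETS,
    NETWORK_LABELS,
    RESPONSE_LABEL,
    build_design,
    dyadic_covariates,
    outcome_similarity_matrix,
)
from .net_model import Network, NodeTable
from .qap_inference import (
    PermutationEngine,
    QapRegressionResult,
    lrqap,
    qap_correlation,
    significance_stars,
)
from .structural_effects import StructuralModes

__all__ = [
    "TABLE_VARIABLES",
    "CorrelationReport",
    "ModelReport",
    "run_correlations",
    "run_models",
    "write_manifest",
]


def _network_terms(context: str) -> list[str]:
    base = NETWORK_LABELS[context]
    return [base] + [
        f"{base}—{suffix}"
        for suffix in ("Reciprocity", "Closure", "Preferential Attachment")
    ]


#: The sixteen dyadic variables of the full correlation table, in report order.
TABLE_VARIABLES: tuple[str, ...] = tuple(
    [RESPONSE_LABEL]
    + _network_terms("school")
    + _network_terms("after_school")
    + list(CONTROL_COVARIATES)
)


# ---------------------------------------------------------------------------
# correlation report
# ---------------------------------------------------------------------------


@dataclass
class CorrelationReport:
    variables: tuple[str, ...]
    r: pd.DataFrame
    p: pd.DataFrame
    degenerate: pd.DataFrame
    n_permutations: int
    modes: dict[str, str]

    def formatted(self) -> pd.DataFrame:
        """Lower-triangular display table: r with stars, dashed diagonal."""
        out = pd.DataFrame(
            "", index=list(self.variables), columns=list(self.variables)
        )
        for i, vi in enumerate(self.variables):
            out.loc[vi, vi] = "-"
            for vj in self.variables[:i]:
                if self.degenerate.loc[vi, vj]:
                    out.loc[vi, vj] = "n/a"
                else:
                    stars = significance_stars(self.p.loc[vi, vj])
                    out.loc[vi, vj] = f"{self.r.loc[vi, vj]:.3f} {stars}".rstrip()
        return out


def run_correlations(
    node_table: NodeTable,
    networks: Mapping[str, Network],
    engine: PermutationEngine | None = None,
    modes: StructuralModes | None = None,
    variables: Sequence[str] | None = None,
) -> CorrelationReport:
    """Pairwise QAP correlations over the dyadic variables of the study.

    Zero-variance variables are flagged per cell rather than failing the
    whole report.
    """
    engine = engine or PermutationEngine()
    modes = modes or StructuralModes()
    variables = tuple(variables) if variables is not None else TABLE_VARIABLES

    matrices = dict(
        dyadic_covariates(
            node_table, networks, [v for v in variables if v != RESPONSE_LABEL], modes
        )
    )
    if RESPONSE_LABEL in variables:
        matrices[RESPONSE_LABEL] = outcome_similarity_matrix(
            node_table.outcome(), node_table.node_ids
        )

    k = len(variables)
    r = pd.DataFrame(np.full((k, k), np.nan), index=variables, columns=variables)
    p = r.copy()
    degenerate = pd.DataFrame(
        np.zeros((k, k), dtype=bool), index=variables, columns=variables
    )
    for i, vi in enumerate(variables):
        r.loc[vi, vi] = 1.0
        for vj in variables[:i]:
            res = qap_correlation(matrices[vi], matrices[vj], engine)
            r.loc[vi, vj] = r.loc[vj, vi] = res.r_obs
            p.loc[vi, vj] = p.loc[vj, vi] = res.p_two_sided
            degenerate.loc[vi, vj] = degenerate.loc[vj, vi] = res.degenerate
    return CorrelationReport(
        variables=variables,
        r=r,
        p=p,
        degenerate=degenerate,
        n_permutations=engine.n_permutations if not engine.exhaustive else -1,
        modes=modes.as_dict(),
    )


# ---------------------------------------------------------------------------
# model report
# ---------------------------------------------------------------------------


@dataclass
class ModelReport:
    results: dict[str, QapRegressionResult]
    modes: dict[str, str]
    scheme: str
    metadata: dict = field(default_factory=dict)

    def row_order(self) -> list[str]:
        rows: list[str] = ["Intercept"]
        for name in self.results:
            for cov in MODEL_PRESETS.get(name, ()):  # preset rows, stable order
                if cov not in rows:
                    rows.append(cov)
        for res in self.results.values():  # custom covariates, if any
            for cov in res.coefficients:
                if cov not in rows:
                    rows.append(cov)
        return rows

    def to_frame(self) -> pd.DataFrame:
        """Display table: 'coef stars (odds ratio)' per cell plus footer rows."""
        cols = list(self.results)
        frame = pd.DataFrame("", index=self.row_order(), columns=cols)
        for name, res in self.results.items():
            for cov, b in res.coefficients.items():
                stars = res.stars(cov)
                cell = f"{b:.3f}{' ' + stars if stars else ''} ({res.odds_ratios[cov]:.3f})"
                frame.loc[cov, name] = cell
        footer = pd.DataFrame("", index=[
            "# Observations", "# Permutations", "Model p-value", "Pseudo R-squared",
        ], columns=cols)
        for name, res in self.results.items():
            footer.loc["# Observations", name] = f"{res.n_obs}"
            footer.loc["# Permutations", name] = f"{res.n_permutations:,}"
            footer.loc["Model p-value", name] = f"{res.model_p:.3f}"
            footer.loc["Pseudo R-squared", name] = f"{res.fit_stat:.3f}"
        return pd.concat([frame, footer])

    def to_dict(self) -> dict:
        payload: dict = {
            "scheme": self.scheme,
            "structural_modes": self.modes,
            "models": {},
        }
        payload.update(self.metadata)
        for name, res in self.results.items():
            payload["models"][name] = {
                "family": res.family,
                "coefficients": res.coefficients,
                "odds_ratios": res.odds_ratios,
                "p_values": {
                    k: (None if np.isnan(v) else v) for k, v in res.p_values.items()
                },
                "model_p": res.model_p,
                "fit_stat": res.fit_stat,
                "fit_stat_name": res.fit_stat_name,
                "n_obs": res.n_obs,
                "n_permutations": res.n_permutations,
                "converged": res.converged,
            }
        return payload


def run_models(
    node_table: NodeTable,
    networks: Mapping[str, Network],
    engine: PermutationEngine | None = None,
    models: Sequence[str] = ("model1", "model2", "model3"),
    scheme: str = "y_permute",
    modes: StructuralModes | None = None,
    custom_covariates: Mapping[str, Sequence[str]] | None = None,
) -> ModelReport:
    """Fit the requested LRQAP models and assemble the report.

    ``models`` names presets; ``custom_covariates`` maps extra model names
    to explicit covariate lists. The same engine settings (and hence the
    same permutation-count footer) apply to every column.
    """
    engine = engine or PermutationEngine()
    modes = modes or StructuralModes()
    specs: dict[str, Sequence[str]] = {name: MODEL_PRESETS[name] for name in models}
    if custom_covariates:
        specs.update(custom_covariates)
    results: dict[str, QapRegressionResult] = {}
    for name, covs in specs.items():
        design = build_design(node_table, networks, covs, modes=modes)
        results[name] = lrqap(design, engine, scheme=scheme)
        results[name].metadata["structural_modes"] = modes.as_dict()
    return ModelReport(results=results, modes=modes.as_dict(), scheme=scheme)


# ---------------------------------------------------------------------------
# manifests
# ---------------------------------------------------------------------------


def _sha256(path) -> str:
    digest = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            digest.update(chunk)
    return digest.hexdigest()


def write_manifest(path, inputs: Sequence, config: Mapping) -> None:
    """Run manifest: input hashes, configuration and package version.

    Deliberately excludes wall-clock time so identical runs produce
    byte-identical manifests.
    """
    manifest = {
        "package": "netqap",
        "version": _version,
        "inputs": {str(p): _sha256(p) for p in inputs},
        "config": dict(config),
    }
    tmp = f"{path}.tmp"
    with open(tmp, "w", encoding="utf-8") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
        fh.write("\n")
    os.replace(tmp, path)
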