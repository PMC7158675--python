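"""Dyadic social-mechanism covariates derived from a friendship network.

Three mechanisms shape who nominates whom in adolescent friendship
networks, and each is expressed here as a dyad-level covariate matrix so
it can enter a network regression alongside attribute homophily terms:

* **reciprocity** — the tendency of a nomination i -> j to be answered by
  j -> i; the covariate for cell (i, j) is simply whether j nominated i,
  i.e. the transpose of the sociomatrix.
* **triadic closure** — the tendency to befriend friends-of-friends; the
  covariate counts the distinct third parties k that close the dyad via a
  directed two-path i -> k -> j (or thresholds the count at >= 1).
* **preferential attachment** — the tendency to nominate already-popular
  peers; the covariate carries the receiver's in-degree (popularity), or
  optionally the product of total degrees.

The mechanisms are computed on the same network context as the model they
enter (school mechanisms from the school network, after-school from the
after-school network). Mode choices are recorded in report metadata since
different network packages operationalise closure and popularity
differently.
"""

from __future__ import annotations

import numpy as np

from .net_model import DyadicMatrix, Network

__all__ = [
    "reciprocity_matrix",
    "closure_matrix",
    "preferential_attachment_matrix",
    "StructuralModes",
]

CLOSURE_MODES = ("count", "binary")
ATTACHMENT_MODES = ("indegree", "degree_product")


def reciprocity_matrix(network: Network, label: str | None = None) -> DyadicMatrix:
    """Mutuality covariate: cell (i, j) = 1 iff j nominated i (transpose)."""
    return DyadicMatrix(
        values=network.adjacency.T.astype(float),
        label=label or f"{network.context} reciprocity",
    )


def closure_matrix(
    network: Network, mode: str = "count", label: str | None = None
) -> DyadicMatrix:
    """Triadic-closure covariate from directed two-paths.

    cell (i, j) = number of distinct third parties k with ties i -> k and
    k -> j. Because the sociomatrix is hollow, the matrix square ``A @ A``
    counts exactly those two-paths with k != i, j; only the diagonal
    (cyclic i -> k -> i paths) must be discarded. ``mode="binary"``
    thresholds the count at >= 1.
    """
    if mode not in CLOSURE_MODES:
        raise ValueError(f"closure mode must be one of {CLOSURE_MODES}, got {mode!r}")
    a = network.adjacency.astype(np.int64)
    two_paths = a @ a
    np.fill_diagonal(two_paths, 0)
    values = (two_paths >= 1).astype(float) if mode == "binary" else two_paths.astype(float)
    return DyadicMatrix(values=values, label=label or f"{network.context} closure")


def preferential_attachment_matrix(
    network: Network, mode: str = "indegree", label: str | None = None
) -> DyadicMatrix:
    """Popularity covariate: by default cell (i, j) = in-degree of the receiver j.

    ``mode="degree_product"`` uses totaldegree(i) * totaldegree(j) instead,
    the undirected-flavoured reading of preferential attachment.
    """
    if mode not in ATTACHMENT_MODES:
        raise ValueError(
            f"attachment mode must be one of {ATTACHMENT_MODES}, got {mode!r}"
        )
    n = network.n
    if mode == "indegree":
        indeg = network.in_degrees().astype(float)
        values = np.tile(indeg, (n, 1))
    else:
        total = (network.in_degrees() + network.out_degrees()).astype(float)
        values = np.outer(total, total)
    return DyadicMatrix(
        values=values, label=label or f"{network.context} preferential attachment"
    )


class StructuralModes:
    """Bundle of mode choices for the mechanism covariates of one analysis."""

    def __init__(self, closure: str = "count", attachment: str = "indegree") -> None:
        if closure not in CLOSURE_MODES:
            raise ValueError(f"closure mode must be one of {CLOSURE_MODES}")
        if attachment not in ATTACHMENT_MODES:
            raise ValueError(f"attachment mode must be one of {ATTACHMENT_MODES}")
        self.closure = closure
        self.attachment = attachment

    def as_dict(self) -> dict[str, str]:
        return {"closure": self.closure, "preferential_attachment": self.attachment}

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        return f"StructuralModes(closure={self.closure!r}, attachment={self.attachment!r})"
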