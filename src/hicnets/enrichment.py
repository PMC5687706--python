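"""Subcompartment-resolved enrichment of domain interactions.

Domains carry one of six subcompartment labels (A1, A2 = active compartment
A; B1, B2, B3 = heterochromatic compartment B; B4 = chr19-specific).  For a
pair of labels (i, j) the mean interaction <H(i,j)> over all domain pairs
with those labels is compared to the background H0, the unweighted mean of
<H(i,j)> over the N_c observed label pairs:

    H_ij = (<H(i,j)> - H0) / H0

so H is dimensionless, can be negative, and averages to zero over the label
pairs by construction.  Homotypic (diagonal) cis enrichment and A1-biased
trans enrichment are the expected signatures on real maps.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .domains import ContactDomain, DomainInteractionMatrix
from .io import SUBCOMPARTMENTS

__all__ = [
    "EnrichmentHeatmap",
    "subcompartment_enrichment",
    "top_interactors",
    "compartment_composition",
]


@dataclass
class EnrichmentHeatmap:
    """Label-pair mean interactions and their background-relative enrichment."""

    labels: list[str]
    mean_I: dict  # (label_i, label_j) sorted tuple -> <H(i,j)>
    enrichment: dict  # same keys -> H_ij
    H0: float
    N_c: int
    scope: str  # 'cis' | 'trans'
    missing_pairs: list

    def to_frame(self, kind: str = "enrichment") -> pd.DataFrame:
        """Square symmetric DataFrame of H (or mean I with kind='mean')."""
        src = self.enrichment if kind == "enrichment" else self.mean_I
        df = pd.DataFrame(np.nan, index=self.labels, columns=self.labels)
        for (i, j), v in src.items():
            df.loc[i, j] = v
            df.loc[j, i] = v
        return df


def _label_pair(a: str, b: str) -> tuple[str, str]:
    return (a, b) if a <= b else (b, a)


def subcompartment_enrichment(nets, scope: str) -> EnrichmentHeatmap:
    """Background-normalized enrichment H_ij over subcompartment pairs.

    ``nets`` is an iterable of :class:`DomainInteractionMatrix` of matching
    ``kind``; unlabeled domains are excluded.  Label pairs with no observed
    domain pair are omitted from the heatmap (and listed), not reported as
    zero.
    """
    sums: dict[tuple[str, str], float] = {}
    counts: dict[tuple[str, str], int] = {}
    present: set[str] = set()
    for net in nets:
        if net.kind != scope:
            raise ValueError(f"network kind {net.kind!r} does not match scope {scope!r}")
        row_lab = [d.subcompartment for d in net.domains_row]
        col_lab = [d.subcompartment for d in net.domains_col]
        present.update(l for l in row_lab + col_lab if l)
        if scope == "cis":
            n = len(row_lab)
            iu, ju = np.triu_indices(n, k=1)
            pairs = zip(iu, ju)
        else:
            pairs = (
                (i, j) for i in range(len(row_lab)) for j in range(len(col_lab))
            )
        V = net.values
        for i, j in pairs:
            li, lj = row_lab[i], col_lab[j]
            if li is None or lj is None:
                continue
            key = _label_pair(li, lj)
            sums[key] = sums.get(key, 0.0) + V[i, j]
            counts[key] = counts.get(key, 0) + 1
    labels = [l for l in SUBCOMPARTMENTS if l in present]
    if len(labels) < 2:
        raise ValueError("fewer than 2 subcompartment labels present")
    mean_I = {k: sums[k] / counts[k] for k in sums}
    n_c = len(mean_I)
    h0 = sum(mean_I.values()) / n_c
    if h0 == 0:
        raise ValueError("zero background mean; enrichment undefined")
    enrich = {k: (v - h0) / h0 for k, v in mean_I.items()}
    missing = [
        (labels[i], labels[j])
        for i in range(len(labels))
        for j in range(i, len(labels))
        if (labels[i], labels[j]) not in mean_I
    ]
    return EnrichmentHeatmap(labels, mean_I, enrich, h0, n_c, scope, missing)


def top_interactors(nets, fraction: float = 0.05, scope: str = "cis"):
    """Domains with the highest mean interaction with their partners.

    Cis: for each domain, the mean I over the other domains of its own
    chromosome.  Trans: the mean I over the domains of all other chromosomes
    (pooled across pairs).  The top ``ceil(fraction * N)`` domains are
    returned, ties at the cut broken by genomic coordinate; returns
    ``(subset, info)`` with the tie flag and per-domain means in ``info``.
    """
    if not 0 < fraction <= 1:
        raise ValueError(f"fraction must lie in (0, 1], got {fraction}")
    totals: dict[str, float] = {}
    partners: dict[str, int] = {}
    domains: dict[str, ContactDomain] = {}

    def add(d: ContactDomain, s: float, k: int):
        domains[d.id] = d
        totals[d.id] = totals.get(d.id, 0.0) + s
        partners[d.id] = partners.get(d.id, 0) + k

    for net in nets:
        if net.kind != scope:
            raise ValueError(f"network kind {net.kind!r} does not match scope {scope!r}")
        if scope == "cis":
            n = len(net.domains_row)
            for d, s in zip(net.domains_row, net.values.sum(axis=1)):
                add(d, float(s), n - 1)
        else:
            for d, s in zip(net.domains_row, net.values.sum(axis=1)):
                add(d, float(s), len(net.domains_col))
            for d, s in zip(net.domains_col, net.values.sum(axis=0)):
                add(d, float(s), len(net.domains_row))
    means = {i: totals[i] / partners[i] for i in totals if partners[i] > 0}
    order = sorted(
        means, key=lambda i: (-means[i], domains[i].chrom, domains[i].start)
    )
    k = math.ceil(fraction * len(order))
    cut = order[:k]
    tie_at_cut = (
        len(order) > k and means[order[k - 1]] == means[order[k]]
    )
    subset = sorted((domains[i] for i in cut), key=lambda d: d.sort_key())
    info = {"means": means, "tie_at_cut": bool(tie_at_cut), "n_selected": k}
    return subset, info


def compartment_composition(domains) -> dict[str, float]:
    """Fraction of domains per subcompartment label; unassigned under 'N.A.'."""
    domains = list(domains)
    if not domains:
        raise ValueError("empty domain set")
    counts: dict[str, int] = {}
    for d in domains:
        label = d.subcompartment or "N.A."
        counts[label] = counts.get(label, 0) + 1
    total = len(domains)
    order = list(SUBCOMPARTMENTS) + ["N.A."]
    return {l: counts[l] / total for l in order if l in counts}
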