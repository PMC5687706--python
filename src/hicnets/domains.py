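"""Contact domains as network nodes and the domain-pair interaction statistic.

A contact domain is a genomic interval called on a Hi-C map (e.g. by
Arrowhead); here domains are the nodes of the chromosome interaction
network.  The edge weight between domains *a* and *b* is

    I(a, b) = sum of shared matrix entries / (L_a * L_b)

with the sum running over the bin block of the two domains in the
(normalized) contact matrix and the lengths in base pairs, so I has units of
intensity per bp^2.  Domains completely contained in another domain
("internal" domains) are removed before any network statistic to avoid
double counting of contacts.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import scipy.sparse as sp

from .io import ContactMatrix, GenomicInterval

__all__ = [
    "ContactDomain",
    "DomainInteractionMatrix",
    "filter_internal_domains",
    "assign_subcompartments",
    "domain_bins",
    "domain_interaction",
    "build_interaction_matrices",
    "cis_trans_ratio",
]


@dataclass(frozen=True)
class ContactDomain:
    """A contact domain: an interval node, optionally subcompartment-labeled."""

    interval: GenomicInterval
    subcompartment: str | None = None

    @property
    def id(self) -> str:
        return str(self.interval)

    @property
    def chrom(self) -> str:
        return self.interval.chrom

    @property
    def start(self) -> int:
        return self.interval.start

    @property
    def end(self) -> int:
        return self.interval.end

    @property
    def length(self) -> int:
        return self.interval.length

    def sort_key(self):
        return (self.chrom, self.start, self.end)


@dataclass
class DomainInteractionMatrix:
    """Weighted adjacency I(a, b) between two ordered domain lists.

    ``kind='cis'``: both axes are the same chromosome's domains, ``values`` is
    symmetric and the diagonal (self-pairs) is held at zero and excluded from
    every pooled distribution.  ``kind='trans'``: rows and columns are domains
    of two different chromosomes.
    """

    domains_row: list[ContactDomain]
    domains_col: list[ContactDomain]
    values: np.ndarray
    kind: str  # 'cis' | 'trans'

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (len(self.domains_row), len(self.domains_col)):
            raise ValueError("values shape does not match domain lists")
        if self.values.size and self.values.min() < 0:
            raise ValueError("negative interaction values")
        if self.kind not in ("cis", "trans"):
            raise ValueError(f"kind must be 'cis' or 'trans', got {self.kind!r}")
        if self.kind == "cis":
            if not np.allclose(self.values, self.values.T):
                raise ValueError("cis interaction matrix must be symmetric")
            np.fill_diagonal(self.values, 0.0)

    @property
    def chrom_row(self) -> str:
        return self.domains_row[0].chrom

    @property
    def chrom_col(self) -> str:
        return self.domains_col[0].chrom

    def pool(self) -> np.ndarray:
        """All distinct-pair interaction values (cis: upper triangle, no diagonal)."""
        if self.kind == "cis":
            iu = np.triu_indices(len(self.domains_row), k=1)
            return self.values[iu]
        return self.values.ravel()

    def shuffled(self, rng) -> "DomainInteractionMatrix":
        """Copy with cell values permuted uniformly at random (same multiset)."""
        if self.kind == "cis":
            n = len(self.domains_row)
            iu = np.triu_indices(n, k=1)
            vals = rng.permutation(self.values[iu])
            out = np.zeros_like(self.values)
            out[iu] = vals
            out = out + out.T
        else:
            out = rng.permutation(self.values.ravel()).reshape(self.values.shape)
        return replace(self, values=out)


# ---------------------------------------------------------------------------
# domain list processing


def filter_internal_domains(domains, return_report: bool = False):
    """Drop domains strictly contained in another domain of the same chromosome.

    Exact duplicate intervals are collapsed to one before the containment
    check, so the operation is idempotent and order-independent.  With
    ``return_report=True`` also returns counts (total, duplicates, internal,
    kept) mirroring the published-list bookkeeping.
    """
    items = sorted(domains, key=lambda d: d.sort_key())
    unique: list[ContactDomain] = []
    for d in items:
        if unique and unique[-1].sort_key() == d.sort_key():
            continue
        unique.append(d)
    kept: list[ContactDomain] = []
    n_internal = 0
    max_end: dict[str, int] = {}
    # sorted by (chrom, start, end): resort with end descending so that any
    # container precedes its contents
    for d in sorted(unique, key=lambda d: (d.chrom, d.start, -d.end)):
        if max_end.get(d.chrom, -1) >= d.end:
            n_internal += 1
            continue
        kept.append(d)
        max_end[d.chrom] = max(max_end.get(d.chrom, -1), d.end)
    kept.sort(key=lambda d: d.sort_key())
    if return_report:
        report = {
            "n_input": len(items),
            "n_duplicates": len(items) - len(unique),
            "n_internal": n_internal,
            "n_kept": len(kept),
            "internal_fraction": n_internal / len(unique) if unique else 0.0,
        }
        return kept, report
    return kept


def assign_subcompartments(domains, annotation, mode: str = "single"):
    """Label each domain with a subcompartment from a BED-like annotation.

    mode='single': a domain is labeled only when every annotation interval it
    overlaps carries one and the same label; otherwise it stays unassigned.
    mode='majority': the label with the largest overlapped bp wins; an exact
    tie leaves the domain unassigned (and is reported).

    Returns ``(labeled_domains, report)`` where the report gives the fraction
    assigned and tie/no-overlap counts.  Annotation intervals overlapping each
    other with different labels raise ``ValueError``.
    """
    if mode not in ("single", "majority"):
        raise ValueError(f"mode must be 'single' or 'majority', got {mode!r}")
    ann = sorted(annotation, key=lambda t: t[0])
    for (a, la), (b, lb) in zip(ann, ann[1:]):
        if a.chrom == b.chrom and b.start < a.end and la != lb:
            raise ValueError(
                f"annotation intervals {a} ({la}) and {b} ({lb}) overlap "
                "with different labels"
            )
    by_chrom: dict[str, list[tuple[GenomicInterval, str]]] = {}
    for iv, label in ann:
        by_chrom.setdefault(iv.chrom, []).append((iv, label))

    labeled: list[ContactDomain] = []
    n_assigned = n_no_overlap = n_ambiguous = n_ties = 0
    for d in domains:
        overlaps: dict[str, int] = {}
        for iv, label in by_chrom.get(d.chrom, ()):
            if iv.start >= d.end:
                break
            bp = iv.overlap(d.interval)
            if bp > 0:
                overlaps[label] = overlaps.get(label, 0) + bp
        label = None
        if not overlaps:
            n_no_overlap += 1
        elif mode == "single":
            if len(overlaps) == 1:
                label = next(iter(overlaps))
            else:
                n_ambiguous += 1
        else:  # majority
            best = max(overlaps.values())
            winners = [l for l, bp in overlaps.items() if bp == best]
            if len(winners) == 1:
                label = winners[0]
            else:
                n_ties += 1
        if label is not None:
            n_assigned += 1
        labeled.append(replace(d, subcompartment=label))
    report = {
        "mode": mode,
        "n_domains": len(labeled),
        "n_assigned": n_assigned,
        "fraction_assigned": n_assigned / len(labeled) if labeled else 0.0,
        "n_no_overlap": n_no_overlap,
        "n_multi_label": n_ambiguous,
        "n_ties": n_ties,
    }
    return labeled, report


# ---------------------------------------------------------------------------
# the interaction statistic


def domain_bins(interval: GenomicInterval, bin_size: int) -> np.ndarray:
    """Bin indices whose midpoints fall inside the interval."""
    first = int(np.ceil(interval.start / bin_size - 0.5))
    last = int(np.ceil(interval.end / bin_size - 0.5))
    return np.arange(max(first, 0), last)


def _check_extent(bins: np.ndarray, n: int, who: str):
    if bins.size == 0 or bins[-1] >= n:
        raise ValueError(f"domain {who} falls outside the matrix extent ({n} bins)")


def domain_interaction(
    matrix: ContactMatrix, a: ContactDomain, b: ContactDomain
) -> float:
    """Average contact frequency I(a,b): shared-entry sum over L_a * L_b."""
    if {a.chrom, b.chrom} != {matrix.chrom_row, matrix.chrom_col}:
        raise ValueError(
            f"domains {a.id}, {b.id} do not match matrix "
            f"({matrix.chrom_row}, {matrix.chrom_col})"
        )
    if a.chrom != matrix.chrom_row:
        a, b = b, a
    rows = domain_bins(a.interval, matrix.bin_size)
    cols = domain_bins(b.interval, matrix.bin_size)
    _check_extent(rows, matrix.shape[0], a.id)
    _check_extent(cols, matrix.shape[1], b.id)
    block = matrix.values[rows[0] : rows[-1] + 1, cols[0] : cols[-1] + 1]
    return float(block.sum()) / (a.length * b.length)


def _indicator(domains, bin_size: int, n_bins: int) -> sp.csr_matrix:
    rows, cols = [], []
    for k, d in enumerate(domains):
        bins = domain_bins(d.interval, bin_size)
        _check_extent(bins, n_bins, d.id)
        rows.extend([k] * len(bins))
        cols.extend(bins.tolist())
    return sp.csr_matrix(
        (np.ones(len(rows)), (rows, cols)), shape=(len(domains), n_bins)
    )


def build_interaction_matrices(
    matrices: dict, domains
) -> tuple[dict, dict]:
    """All pairwise I(a,b): one cis matrix per chromosome, one trans per pair.

    ``matrices`` maps ``(chrom_row, chrom_col)`` to a :class:`ContactMatrix`
    (cis entries keyed ``(c, c)``); a matrix missing for a needed chromosome
    pair raises ``KeyError`` naming the pair.  Returns ``(cis, trans)`` dicts
    keyed by chromosome and by sorted chromosome pair.
    """
    by_chrom: dict[str, list[ContactDomain]] = {}
    for d in sorted(domains, key=lambda d: d.sort_key()):
        by_chrom.setdefault(d.chrom, []).append(d)
    chroms = list(by_chrom)

    def get_matrix(c1, c2) -> ContactMatrix:
        for key in ((c1, c2), (c2, c1)):
            if key in matrices:
                return matrices[key]
        raise KeyError(f"no contact matrix for chromosome pair ({c1}, {c2})")

    cis: dict[str, DomainInteractionMatrix] = {}
    trans: dict[tuple[str, str], DomainInteractionMatrix] = {}
    for c in chroms:
        mat = get_matrix(c, c)
        doms = by_chrom[c]
        B = _indicator(doms, mat.bin_size, mat.shape[0])
        sums = np.asarray((B @ mat.values @ B.T).todense())
        L = np.array([d.length for d in doms], dtype=float)
        vals = sums / np.outer(L, L)
        np.fill_diagonal(vals, 0.0)
        cis[c] = DomainInteractionMatrix(doms, doms, vals, "cis")
    for i, c1 in enumerate(chroms):
        for c2 in chroms[i + 1 :]:
            mat = get_matrix(c1, c2)
            if mat.chrom_row != c1:  # orient rows to c1
                mat = ContactMatrix(
                    c1, c2, mat.bin_size, mat.values.T, normalized=mat.normalized
                )
            dr, dc = by_chrom[c1], by_chrom[c2]
            Br = _indicator(dr, mat.bin_size, mat.shape[0])
            Bc = _indicator(dc, mat.bin_size, mat.shape[1])
            sums = np.asarray((Br @ mat.values @ Bc.T).todense())
            Lr = np.array([d.length for d in dr], dtype=float)
            Lc = np.array([d.length for d in dc], dtype=float)
            trans[(c1, c2)] = DomainInteractionMatrix(
                dr, dc, sums / np.outer(Lr, Lc), "trans"
            )
    return cis, trans


def cis_trans_ratio(cis_values, trans_values) -> float:
    """Mean in-cis interaction over mean in-trans interaction."""
    cis_values = np.asarray(cis_values, dtype=float)
    trans_values = np.asarray(trans_values, dtype=float)
    if cis_values.size == 0 or trans_values.size == 0:
        raise ValueError("both interaction pools must be non-empty")
    mt = trans_values.mean()
    if mt == 0:
        raise ValueError("trans pool mean is zero; ratio undefined")
    return float(cis_values.mean() / mt)
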