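"""Distributed spectral counting (uSpC, dSpC) and dNSAF per run.

Shared peptides' spectra are apportioned among their parent proteins in
proportion to each parent's unique spectral count:

    dSpC_k = uSpC_k + sum_j SpC_j * uSpC_k / sum_{i in parents(j)} uSpC_i

over shared peptides j.  The distributed counts are then length-normalized
into distributed Normalized Spectral Abundance Factors,

    dNSAF_k = (dSpC_k / L_k) / sum_i (dSpC_i / L_i),

which sum to one within a run and serve as relative abundance estimates.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .psm_filter import PeptideSpectrumMatch
from .sequence_db import DigestPeptide, mapping_index


@dataclass(frozen=True)
class ProteinQuant:
    accession: str
    run_id: str
    u_spc: float
    d_spc: float
    dnsaf: float


@dataclass
class ConditionCountMatrix:
    """Per-protein dSpC (and companion dNSAF) across named runs/conditions."""

    dspc: pd.DataFrame  # rows: accessions, columns: run labels
    dnsaf: pd.DataFrame

    def __post_init__(self) -> None:
        if (self.dspc.to_numpy() < 0).any():
            raise ValueError("negative dSpC cell")

    @property
    def runs(self) -> list[str]:
        return list(self.dspc.columns)


def _accepted_parents(
    dp: DigestPeptide, accepted_proteins: set[str]
) -> frozenset[str]:
    return frozenset(a for a in dp.parents if a in accepted_proteins)


def count_spectra(
    psms: Sequence[PeptideSpectrumMatch],
    mapping: Sequence[DigestPeptide] | Mapping[str, DigestPeptide],
    accepted_proteins: set[str],
) -> tuple[dict[str, int], dict[str, float]]:
    """Per-peptide spectral counts and per-protein unique counts for one run.

    Spectra of peptides mapping to no accepted protein are excluded from
    counting (and hence from the conservation total): only detected proteins
    are quantified.
    """
    index = mapping if isinstance(mapping, Mapping) else mapping_index(mapping)
    spc: dict[str, int] = {}
    for psm in psms:
        dp = index.get(psm.peptide)
        if dp is None or not _accepted_parents(dp, accepted_proteins):
            continue
        spc[psm.peptide] = spc.get(psm.peptide, 0) + 1
    u_spc: dict[str, float] = {acc: 0.0 for acc in accepted_proteins}
    for pep, n in spc.items():
        parents = _accepted_parents(index[pep], accepted_proteins)
        if len(parents) == 1:
            (acc,) = parents
            u_spc[acc] += n
    return spc, u_spc


def distribute_counts(
    peptide_counts: Mapping[str, int],
    mapping: Sequence[DigestPeptide] | Mapping[str, DigestPeptide],
    u_spc: Mapping[str, float],
) -> dict[str, float]:
    """Apportion shared spectra proportionally to the sharers' unique counts.

    If every sharer of a peptide has zero unique spectra, its count is split
    equally among them, preserving the conservation of total counted spectra.
    """
    index = mapping if isinstance(mapping, Mapping) else mapping_index(mapping)
    accepted = set(u_spc)
    d_spc: dict[str, float] = dict(u_spc)
    for pep, n in peptide_counts.items():
        parents = _accepted_parents(index[pep], accepted)
        if len(parents) <= 1:
            continue  # unique spectra already inside u_spc
        total_u = sum(u_spc[a] for a in parents)
        for acc in parents:
            share = u_spc[acc] / total_u if total_u > 0 else 1.0 / len(parents)
            d_spc[acc] += n * share
    return d_spc


def compute_dnsaf(
    d_spc: Mapping[str, float], lengths: Mapping[str, int]
) -> dict[str, float]:
    """Length-normalize distributed counts; the result sums to 1 per run."""
    for acc in d_spc:
        if lengths[acc] <= 0:
            raise ValueError(f"{acc}: non-positive length")
    saf = {acc: v / lengths[acc] for acc, v in d_spc.items()}
    total = sum(saf.values())
    if total <= 0:
        raise ValueError("empty run: no counted spectra")
    return {acc: v / total for acc, v in saf.items()}


def quantify_run(
    psms: Sequence[PeptideSpectrumMatch],
    mapping: Sequence[DigestPeptide] | Mapping[str, DigestPeptide],
    accepted_proteins: set[str],
    lengths: Mapping[str, int],
    run_id: str,
) -> list[ProteinQuant]:
    """uSpC / dSpC / dNSAF for every accepted protein in one run.

    Runs in which nothing was counted yield all-zero dSpC and zero dNSAF
    (the dNSAF normalization is undefined there and reported as 0).
    """
    index = mapping if isinstance(mapping, Mapping) else mapping_index(mapping)
    run_psms = [p for p in psms if p.run_id == run_id]
    spc, u_spc = count_spectra(run_psms, index, accepted_proteins)
    d_spc = distribute_counts(spc, index, u_spc)
    if sum(d_spc.values()) > 0:
        dnsaf = compute_dnsaf(d_spc, lengths)
    else:
        dnsaf = {acc: 0.0 for acc in d_spc}
    return [
        ProteinQuant(acc, run_id, u_spc[acc], d_spc[acc], dnsaf[acc])
        for acc in sorted(accepted_proteins)
    ]


def build_count_matrix(
    quants: Iterable[ProteinQuant], runs: Sequence[str]
) -> ConditionCountMatrix:
    """Column-bind per-run quantifications into condition matrices.

    Runs are never summed; the co-enrichment classifier needs per-fraction
    values.  Missing (protein, run) cells are zero.
    """
    quants = list(quants)
    accs = sorted({q.accession for q in quants})
    dspc = pd.DataFrame(0.0, index=accs, columns=list(runs))
    dnsaf = pd.DataFrame(0.0, index=accs, columns=list(runs))
    for q in quants:
        if q.run_id not in dspc.columns:
            raise KeyError(f"run {q.run_id!r} not in design columns {list(runs)}")
        dspc.loc[q.accession, q.run_id] = q.d_spc
        dnsaf.loc[q.accession, q.run_id] = q.dnsaf
    return ConditionCountMatrix(dspc=dspc, dnsaf=dnsaf)


def write_quant_report(quants: Iterable[ProteinQuant], path: str | Path) -> None:
    df = pd.DataFrame(
        [(q.accession, q.run_id, q.u_spc, q.d_spc, q.dnsaf) for q in quants],
        columns=["accession", "run_id", "u_spc", "d_spc", "dnsaf"],
    )
    df.to_csv(path, sep="\t", index=False)


def write_count_matrix(matrix: ConditionCountMatrix, path: str | Path) -> None:
    """Wide-format TSV mirroring the candidate-table layout; dSpC cells are
    rounded to integers for display, dNSAF kept at full precision."""
    out = matrix.dspc.round(0).astype(int).copy()
    out.columns = [f"{c}_dspc" for c in out.columns]
    dn = matrix.dnsaf.copy()
    dn.columns = [f"{c}_dnsaf" for c in dn.columns]
    pd.concat([out, dn], axis=1).rename_axis("accession").to_csv(path, sep="\t")
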