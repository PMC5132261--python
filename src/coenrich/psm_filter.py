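"""DTASelect-style PSM acceptance criteria and decoy-based FDR estimation.

A peptide-spectrum match (PSM) is retained only if its SEQUEST quality
scores clear charge-specific thresholds (XCorr) and a minimum DeltCn, the
peptide is long enough, and at least one parent occurrence is fully
tryptic.  Proteins are then accepted if, pooling all runs, they are
supported by two distinct peptides or by one peptide with two independent
spectra.  Decoy hits among accepted PSMs estimate the false discovery rate.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .sequence_db import DigestPeptide, mapping_index

# rejection reason codes, in evaluation order
REASON_UNMAPPED = "unmapped"
REASON_LENGTH = "length"
REASON_TRYPTIC = "tryptic"
REASON_DELTCN = "deltcn"
REASON_XCORR = "xcorr"


@dataclass
class PeptideSpectrumMatch:
    """One spectrum's best peptide assignment."""

    run_id: str
    scan_id: int
    peptide: str
    charge: int
    xcorr: float
    delt_cn: float
    is_decoy: bool = False

    def __post_init__(self) -> None:
        if not self.peptide:
            raise ValueError("empty peptide")
        if self.charge < 1:
            raise ValueError("charge must be >= 1")
        self.peptide = self.peptide.upper()


@dataclass(frozen=True)
class FilterThresholds:
    """Acceptance thresholds; all comparisons are inclusive ('at least')."""

    min_delt_cn: float = 0.08
    min_xcorr_by_charge: Mapping[int, float] = field(
        default_factory=lambda: {1: 1.8, 2: 2.0, 3: 3.0}
    )
    min_peptide_length: int = 7
    require_fully_tryptic: bool = True
    #: charges above the highest configured one reuse the highest charge's
    #: XCorr threshold (conservative extension); set False to error instead.
    extend_to_higher_charges: bool = True

    def xcorr_threshold(self, charge: int) -> float:
        if charge in self.min_xcorr_by_charge:
            return self.min_xcorr_by_charge[charge]
        top = max(self.min_xcorr_by_charge)
        if self.extend_to_higher_charges and charge > top:
            return self.min_xcorr_by_charge[top]
        raise KeyError(f"no XCorr threshold configured for charge {charge}")


@dataclass
class FilterResult:
    accepted: list[PeptideSpectrumMatch]
    rejected: list[tuple[PeptideSpectrumMatch, str]]

    @property
    def reasons(self) -> dict[str, int]:
        counts: dict[str, int] = {}
        for _, reason in self.rejected:
            counts[reason] = counts.get(reason, 0) + 1
        return counts


def assign_decoy_status(
    psms: Iterable[PeptideSpectrumMatch],
    mapping: Sequence[DigestPeptide] | Mapping[str, DigestPeptide],
    decoy_prefix: str = "DECOY_",
) -> None:
    """Set ``is_decoy`` in place: a PSM is a decoy hit only if every parent
    is a decoy (a peptide shared with any target is tie-broken to target,
    the standard concatenated-search convention)."""
    index = mapping if isinstance(mapping, Mapping) else mapping_index(mapping)
    for psm in psms:
        dp = index.get(psm.peptide)
        if dp is None or not dp.occurrences:
            psm.is_decoy = False
            continue
        psm.is_decoy = all(
            o.accession.startswith(decoy_prefix) for o in dp.occurrences
        )


def filter_psms(
    psms: Sequence[PeptideSpectrumMatch],
    mapping: Sequence[DigestPeptide] | Mapping[str, DigestPeptide],
    thresholds: FilterThresholds | None = None,
) -> FilterResult:
    """Apply the spectrum-level acceptance criteria.

    A PSM is accepted iff DeltCn >= min_delt_cn, XCorr >= the charge's
    threshold, peptide length >= min_peptide_length, and (if required) at
    least one parent occurrence is fully tryptic.  PSMs whose peptide is not
    in the mapping are rejected as ``unmapped``.  Each rejection carries the
    first failing reason code.
    """
    thresholds = thresholds or FilterThresholds()
    index = mapping if isinstance(mapping, Mapping) else mapping_index(mapping)
    accepted: list[PeptideSpectrumMatch] = []
    rejected: list[tuple[PeptideSpectrumMatch, str]] = []
    for psm in psms:
        dp = index.get(psm.peptide)
        if dp is None or not dp.occurrences:
            rejected.append((psm, REASON_UNMAPPED))
            continue
        if len(psm.peptide) < thresholds.min_peptide_length:
            rejected.append((psm, REASON_LENGTH))
            continue
        if thresholds.require_fully_tryptic and not dp.is_fully_tryptic:
            rejected.append((psm, REASON_TRYPTIC))
            continue
        if psm.delt_cn < thresholds.min_delt_cn:
            rejected.append((psm, REASON_DELTCN))
            continue
        if psm.xcorr < thresholds.xcorr_threshold(psm.charge):
            rejected.append((psm, REASON_XCORR))
            continue
        accepted.append(psm)
    return FilterResult(accepted=accepted, rejected=rejected)


def accept_proteins(
    accepted: Sequence[PeptideSpectrumMatch],
    mapping: Sequence[DigestPeptide] | Mapping[str, DigestPeptide],
) -> set[str]:
    """Protein-level acceptance, pooling all runs.

    A protein is accepted iff it has >= 2 distinct accepted peptide
    sequences, or 1 peptide supported by >= 2 independent spectra
    (distinct (run_id, scan_id) pairs).
    """
    index = mapping if isinstance(mapping, Mapping) else mapping_index(mapping)
    peptides_of: dict[str, set[str]] = {}
    spectra_of: dict[str, set[tuple[str, int]]] = {}
    for psm in accepted:
        dp = index.get(psm.peptide)
        if dp is None:
            continue
        for acc in dp.parents:
            peptides_of.setdefault(acc, set()).add(psm.peptide)
            spectra_of.setdefault(acc, set()).add((psm.run_id, psm.scan_id))
    return {
        acc
        for acc, peps in peptides_of.items()
        if len(peps) >= 2 or len(spectra_of[acc]) >= 2
    }


@dataclass(frozen=True)
class FdrEstimate:
    """Decoy-based FDR among accepted PSMs.

    ``fdr`` is the classical concatenated-search estimate D/T; the
    symmetric variant 2D/(T+D) is reported alongside.
    """

    fdr: float
    fdr_symmetric: float
    decoy_count: int
    target_count: int
    per_run: dict[str, float]
    empty: bool = False


def estimate_fdr(accepted: Sequence[PeptideSpectrumMatch]) -> FdrEstimate:
    """Estimate the false discovery rate from decoy hits among accepted PSMs."""
    decoys = sum(1 for p in accepted if p.is_decoy)
    targets = len(accepted) - decoys
    per_run: dict[str, float] = {}
    runs: dict[str, list[PeptideSpectrumMatch]] = {}
    for p in accepted:
        runs.setdefault(p.run_id, []).append(p)
    for run_id, psms in runs.items():
        d = sum(1 for p in psms if p.is_decoy)
        per_run[run_id] = d / max(len(psms) - d, 1)
    total = decoys + targets
    return FdrEstimate(
        fdr=decoys / max(targets, 1),
        fdr_symmetric=(2 * decoys / total) if total else 0.0,
        decoy_count=decoys,
        target_count=targets,
        per_run=per_run,
        empty=(total == 0),
    )


# ---------------------------------------------------------------------------
# tab-delimited IO

PSM_COLUMNS = ["run_id", "scan_id", "peptide", "charge", "xcorr", "delt_cn"]


def read_psm_table(path: str | Path) -> list[PeptideSpectrumMatch]:
    df = pd.read_csv(path, sep="\t")
    missing = [c for c in PSM_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing PSM column(s) {missing}")
    return [
        PeptideSpectrumMatch(
            run_id=str(r.run_id),
            scan_id=int(r.scan_id),
            peptide=str(r.peptide),
            charge=int(r.charge),
            xcorr=float(r.xcorr),
            delt_cn=float(r.delt_cn),
        )
        for r in df.itertuples(index=False)
    ]


def psms_to_frame(psms: Sequence[PeptideSpectrumMatch]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            (p.run_id, p.scan_id, p.peptide, p.charge, p.xcorr, p.delt_cn, p.is_decoy)
            for p in psms
        ],
        columns=PSM_COLUMNS + ["is_decoy"],
    )


def write_filter_report(result: FilterResult, path: str | Path) -> None:
    """PSM table plus ``accepted`` and ``reason`` columns."""
    rows = [
        (p.run_id, p.scan_id, p.peptide, p.charge, p.xcorr, p.delt_cn, True, "")
        for p in result.accepted
    ] + [
        (p.run_id, p.scan_id, p.peptide, p.charge, p.xcorr, p.delt_cn, False, reason)
        for p, reason in result.rejected
    ]
    df = pd.DataFrame(rows, columns=PSM_COLUMNS + ["accepted", "reason"])
    df.to_csv(path, sep="\t", index=False)
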