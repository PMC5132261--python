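"""Dual-criteria co-enrichment classifier for bait-complex candidates.

A protein is called a candidate interactor when it satisfies both of two
independent enrichment criteria on its distributed spectral counts (dSpC):

* fractionation: absent from the low-salt (210 mM) anion-exchange fraction,
  detected in the bait-enriched 290 mM fraction, and at least ``fold``
  (default 5) times more spectra in 290 mM than in 350 mM;
* immunoprecipitation: detected in at least one bait-antibody IP replicate
  and in no control-IgG replicate.

The conjunction is deliberately strict: each criterion alone admits
abundant co-fractionating contaminants or sticky IP background, but a
protein that co-elutes with the bait on charge AND co-precipitates with it
is a strong candidate.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources
from pathlib import Path
from typing import Sequence

import pandas as pd

from .spectral_quant import ConditionCountMatrix

# reason codes
R_FRAC_OK = "frac-ok"
R_PRESENT_210 = "present-in-210"
R_ABSENT_290 = "absent-in-290"
R_FOLD = "fold-below-threshold"
R_IP_OK = "ip-ok"
R_NO_BAIT = "no-bait-detection"
R_PRESENT_CONTROL = "present-in-control"


@dataclass(frozen=True)
class ExperimentDesign:
    """Which run labels play which role, plus classifier policy knobs."""

    f210: str = "F210"
    f290: str = "F290"
    f350: str = "F350"
    bait_runs: tuple[str, ...] = ("BAIT1", "BAIT2")
    control_runs: tuple[str, ...] = ("CTRL1", "CTRL2")
    fold_threshold: float = 5.0
    #: "any": presence in >=1 bait replicate suffices; "all": every replicate
    bait_policy: str = "any"
    #: a zero 350 mM count passes the fold criterion whenever 290 mM > 0
    zero_denominator_passes: bool = True

    def __post_init__(self) -> None:
        labels = [self.f210, self.f290, self.f350, *self.bait_runs, *self.control_runs]
        if len(set(labels)) != len(labels):
            raise ValueError("design run labels must be disjoint")
        if self.fold_threshold <= 0:
            raise ValueError("fold_threshold must be > 0")
        if self.bait_policy not in ("any", "all"):
            raise ValueError("bait_policy must be 'any' or 'all'")

    @property
    def all_runs(self) -> list[str]:
        return [self.f210, self.f290, self.f350, *self.bait_runs, *self.control_runs]


@dataclass(frozen=True)
class CandidateCall:
    accession: str
    frac_positive: bool
    ip_positive: bool
    reasons: tuple[str, ...]

    @property
    def combined_positive(self) -> bool:
        return self.frac_positive and self.ip_positive


def classify_fractionation(
    c210: float,
    c290: float,
    c350: float,
    fold_threshold: float = 5.0,
    zero_denominator_passes: bool = True,
) -> tuple[bool, str]:
    """Fractionation positivity from the three salt-elution dSpC values.

    True iff c210 == 0, c290 > 0, and c290 >= fold_threshold * c350.  A zero
    350 mM count passes by default: a protein seen only in the bait-enriched
    fraction is maximally enriched, not undefined.
    """
    if min(c210, c290, c350) < 0:
        raise ValueError("negative spectral count")
    if c210 > 0:
        return False, R_PRESENT_210
    if c290 <= 0:
        return False, R_ABSENT_290
    if c350 == 0:
        return (True, R_FRAC_OK) if zero_denominator_passes else (False, R_FOLD)
    if c290 >= fold_threshold * c350:
        return True, R_FRAC_OK
    return False, R_FOLD


def classify_ip(
    bait_counts: Sequence[float],
    control_counts: Sequence[float],
    bait_policy: str = "any",
) -> tuple[bool, str]:
    """IP positivity: present in bait IP(s), absent from every control IgG IP."""
    if any(c > 0 for c in control_counts):
        return False, R_PRESENT_CONTROL
    detected = [c > 0 for c in bait_counts]
    ok = all(detected) if bait_policy == "all" else any(detected)
    return (True, R_IP_OK) if ok else (False, R_NO_BAIT)


def combine_calls(
    accession: str, frac: tuple[bool, str], ip: tuple[bool, str]
) -> CandidateCall:
    return CandidateCall(
        accession=accession,
        frac_positive=frac[0],
        ip_positive=ip[0],
        reasons=(frac[1], ip[1]),
    )


def classify_protein(
    accession: str, counts: pd.Series, design: ExperimentDesign
) -> CandidateCall:
    frac = classify_fractionation(
        counts[design.f210],
        counts[design.f290],
        counts[design.f350],
        design.fold_threshold,
        design.zero_denominator_passes,
    )
    ip = classify_ip(
        [counts[r] for r in design.bait_runs],
        [counts[r] for r in design.control_runs],
        design.bait_policy,
    )
    return combine_calls(accession, frac, ip)


def make_report(
    matrix: ConditionCountMatrix, design: ExperimentDesign
) -> pd.DataFrame:
    """One row per protein with both calls, ordered for human review.

    Combined positives come first, then fractionation-only, then IP-only,
    then negatives; within each block, descending 290 mM dSpC, ties broken
    by accession.
    """
    missing = [r for r in design.all_runs if r not in matrix.dspc.columns]
    if missing:
        raise KeyError(f"count matrix is missing design column(s): {missing}")
    rows = []
    for acc in matrix.dspc.index:
        call = classify_protein(acc, matrix.dspc.loc[acc], design)
        rows.append(
            {
                "accession": acc,
                "f210": matrix.dspc.loc[acc, design.f210],
                "f290": matrix.dspc.loc[acc, design.f290],
                "f350": matrix.dspc.loc[acc, design.f350],
                **{f"bait{i+1}": matrix.dspc.loc[acc, r] for i, r in enumerate(design.bait_runs)},
                **{f"ctrl{i+1}": matrix.dspc.loc[acc, r] for i, r in enumerate(design.control_runs)},
                "frac_positive": call.frac_positive,
                "ip_positive": call.ip_positive,
                "combined_positive": call.combined_positive,
                "reasons": ";".join(call.reasons),
            }
        )
    df = pd.DataFrame(rows)
    if df.empty:
        return df
    block = (
        3 * df["combined_positive"].astype(int)
        + 2 * (df["frac_positive"] & ~df["combined_positive"]).astype(int)
        + 1 * (df["ip_positive"] & ~df["combined_positive"]).astype(int)
    )
    df = (
        df.assign(_block=block)
        .sort_values(["_block", "f290", "accession"], ascending=[False, False, True])
        .drop(columns="_block")
        .reset_index(drop=True)
    )
    return df


def write_report(report: pd.DataFrame, path: str | Path) -> None:
    report.to_csv(path, sep="\t", index=False)


def load_table1() -> ConditionCountMatrix:
    """The packaged candidate-table fixture (printed dSpC/dNSAF cells of the
    published co-enrichment table; blank cells are zero counts)."""
    with resources.files("coenrich.data").joinpath("table1_dspc.tsv").open() as fh:
        df = pd.read_csv(fh, sep="\t", index_col="protein")
    runs = ["F210", "F290", "F350", "BAIT1", "BAIT2", "CTRL1", "CTRL2"]
    dspc = df[[f"{r}_dspc" for r in runs]].fillna(0.0)
    dspc.columns = runs
    dnsaf = df[[f"{r}_dnsaf" for r in runs]].fillna(0.0)
    dnsaf.columns = runs
    return ConditionCountMatrix(dspc=dspc.astype(float), dnsaf=dnsaf.astype(float))


def read_count_matrix(path: str | Path, runs: Sequence[str]) -> ConditionCountMatrix:
    """Read a wide-format dSpC matrix (columns ``<run>_dspc``/``<run>_dnsaf``
    or bare run labels).

    Only the design runs whose columns are present are loaded; a missing run
    is reported by the classifier, which knows the full design."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    bare = [r for r in runs if r in df.columns]
    suffixed = [r for r in runs if f"{r}_dspc" in df.columns]
    if bare:
        dspc = df[bare].fillna(0.0).astype(float)
        dnsaf = pd.DataFrame(0.0, index=df.index, columns=bare)
    elif suffixed:
        dspc = df[[f"{r}_dspc" for r in suffixed]].fillna(0.0).astype(float)
        dspc.columns = suffixed
        dnsaf = pd.DataFrame(0.0, index=df.index, columns=suffixed)
        for r in suffixed:
            if f"{r}_dnsaf" in df.columns:
                dnsaf[r] = df[f"{r}_dnsaf"].fillna(0.0).astype(float)
    else:
        raise KeyError(f"{path}: no dSpC columns for any of the runs {list(runs)}")
    return ConditionCountMatrix(dspc=dspc, dnsaf=dnsaf)
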