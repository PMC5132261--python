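import dataclasses

import numpy as np
import pytest

from coenrich.psm_filter import (
    FilterThresholds,
    PeptideSpectrumMatch,
    accept_proteins,
    assign_decoy_status,
    estimate_fdr,
    filter_psms,
)
from coenrich.sequence_db import DigestPeptide, PeptideOccurrence


def make_dp(pep, parents, status="fully"):
    return DigestPeptide(
        pep,
        [
            PeptideOccurrence(acc, 0, len(pep), status if isinstance(status, str) else status[i])
            for i, acc in enumerate(parents)
        ],
    )


def psm(pep="PEPTIDEK", charge=2, xcorr=2.5, delt_cn=0.2, run="r1", scan=0):
    return PeptideSpectrumMatch(run, scan, pep, charge, xcorr, delt_cn)


MAPPING = [
    make_dp("PEPTIDEK", ["A"]),
    make_dp("SHORTK", ["A"]),  # 6 residues
    make_dp("NONTRYPTIC", ["B"], status="non"),
    make_dp("HALFANDFULL", ["B", "C"], status=["non", "fully"]),
]


class TestFilterPsms:
    def test_thresholds_are_inclusive(self):
        ok = psm(xcorr=2.0, delt_cn=0.08)
        res = filter_psms([ok], MAPPING)
        assert res.accepted == [ok]

    @pytest.mark.parametrize(
        "kwargs,reason",
        [
            (dict(xcorr=1.999), "xcorr"),
            (dict(delt_cn=0.0799), "deltcn"),
            (dict(pep="SHORTK"), "length"),
            (dict(pep="NONTRYPTIC"), "tryptic"),
            (dict(pep="UNKNOWNPEPTIDE"), "unmapped"),
        ],
    )
    def test_rejection_reasons(self, kwargs, reason):
        res = filter_psms([psm(**kwargs)], MAPPING)
        assert not res.accepted
        assert res.rejected[0][1] == reason

    def test_any_fully_tryptic_occurrence_suffices(self):
        res = filter_psms([psm(pep="HALFANDFULL")], MAPPING)
        assert len(res.accepted) == 1

    def test_charge_above_configured_uses_top_threshold(self):
        ok = psm(charge=4, xcorr=3.0)
        low = psm(charge=4, xcorr=2.99, scan=1)
        res = filter_psms([ok, low], MAPPING)
        assert res.accepted == [ok]

    def test_unconfigured_charge_errors_when_extension_disabled(self):
        thresholds = FilterThresholds(extend_to_higher_charges=False)
        with pytest.raises(KeyError, match="charge 4"):
            filter_psms([psm(charge=4)], MAPPING, thresholds)

    def test_matches_independent_predicate_on_simulated_psms(self, rng):
        peptides = {dp.sequence: dp for dp in MAPPING}
        thresholds = FilterThresholds()
        psms = [
            PeptideSpectrumMatch(
                run_id="r1",
                scan_id=i,
                peptide=str(rng.choice(list(peptides) + ["ABSENTPEPTIDE"])),
                charge=int(rng.integers(1, 5)),
                xcorr=float(rng.uniform(0, 5)),
                delt_cn=float(rng.uniform(0, 0.3)),
            )
            for i in range(1000)
        ]
        got = {p.scan_id for p in filter_psms(psms, MAPPING, thresholds).accepted}

        def oracle(p):  # independent re-statement of the four criteria
            dp = peptides.get(p.peptide)
            if dp is None:
                return False
            xthr = {1: 1.8, 2: 2.0, 3: 3.0}.get(p.charge, 3.0)
            return (
                p.delt_cn >= 0.08
                and p.xcorr >= xthr
                and len(p.peptide) >= 7
                and any(o.tryptic_status == "fully" for o in dp.occurrences)
            )

        assert got == {p.scan_id for p in psms if oracle(p)}

    def test_idempotent(self, rng):
        psms = [
            psm(xcorr=float(x), delt_cn=float(d), scan=i)
            for i, (x, d) in enumerate(zip(rng.uniform(0, 4, 200), rng.uniform(0, 0.3, 200)))
        ]
        first = filter_psms(psms, MAPPING)
        again = filter_psms(first.accepted, MAPPING)
        assert again.accepted == first.accepted and not again.rejected

    @pytest.mark.parametrize(
        "change",
        [
            dict(min_delt_cn=0.12),
            dict(min_xcorr_by_charge={1: 2.2, 2: 2.4, 3: 3.4}),
            dict(min_peptide_length=9),
            dict(require_fully_tryptic=True),
        ],
    )
    def test_raising_any_threshold_shrinks_accepted_set(self, rng, change):
        base = FilterThresholds(require_fully_tryptic=False)
        psms = [
            PeptideSpectrumMatch(
                "r1", i, str(rng.choice([dp.sequence for dp in MAPPING])),
                int(rng.integers(1, 4)), float(rng.uniform(0, 4)), float(rng.uniform(0, 0.3)),
            )
            for i in range(500)
        ]
        loose = {p.scan_id for p in filter_psms(psms, MAPPING, base).accepted}
        strict_t = dataclasses.replace(base, **change)
        strict = {p.scan_id for p in filter_psms(psms, MAPPING, strict_t).accepted}
        assert strict <= loose


class TestAcceptProteins:
    def test_two_distinct_peptides_accepts(self):
        mapping = [make_dp("PEPTIDEK", ["A"]), make_dp("ANOTHERK", ["A"])]
        psms = [psm(), psm(pep="ANOTHERK", scan=1)]
        assert accept_proteins(psms, mapping) == {"A"}

    def test_one_peptide_two_spectra_across_runs_accepts(self):
        psms = [psm(run="r1", scan=0), psm(run="r2", scan=0)]
        assert accept_proteins(psms, MAPPING) == {"A"}

    def test_one_peptide_one_spectrum_rejected(self):
        assert accept_proteins([psm()], MAPPING) == set()

    def test_unique_peptides_reduce_to_groupby_oracle(self, rng):
        # <=50 proteins, every peptide unique to one protein
        mapping = []
        psms = []
        scan = 0
        truth_peps: dict[str, set] = {}
        truth_spectra: dict[str, int] = {}
        for i in range(50):
            acc = f"P{i}"
            n_pep = int(rng.integers(1, 4))
            truth_peps[acc] = set()
            truth_spectra[acc] = 0
            for j in range(n_pep):
                pep = f"PEPTIDE{i}X{j}K"
                mapping.append(make_dp(pep, [acc]))
                truth_peps[acc].add(pep)
                for _ in range(int(rng.integers(1, 3))):
                    psms.append(psm(pep=pep, scan=scan))
                    truth_spectra[acc] += 1
                    scan += 1
        expected = {
            acc
            for acc in truth_peps
            if len(truth_peps[acc]) >= 2 or truth_spectra[acc] >= 2
        }
        assert accept_proteins(psms, mapping) == expected


class TestFdr:
    def test_classical_estimate(self):
        psms = [psm(scan=i) for i in range(95)]
        for p in psms[:5]:
            p.is_decoy = True
        est = estimate_fdr(psms)
        assert est.decoy_count == 5 and est.target_count == 90
        assert est.fdr == pytest.approx(5 / 90)
        assert est.fdr_symmetric == pytest.approx(10 / 95)

    def test_no_decoys_gives_zero(self):
        assert estimate_fdr([psm()]).fdr == 0.0

    def test_empty_set_flagged(self):
        est = estimate_fdr([])
        assert est.fdr == 0.0 and est.empty

    def test_per_run_breakdown(self):
        a, b = psm(run="r1"), psm(run="r2", scan=1)
        b.is_decoy = True
        est = estimate_fdr([a, b])
        assert est.per_run == {"r1": 0.0, "r2": 1.0}


class TestDecoyAssignment:
    def test_target_decoy_tiebreak_goes_to_target(self):
        mapping = [
            make_dp("ONLYDECOYK", ["DECOY_X"]),
            make_dp("SHAREDPEPK", ["DECOY_X", "A"]),
        ]
        p1, p2 = psm(pep="ONLYDECOYK"), psm(pep="SHAREDPEPK", scan=1)
        assign_decoy_status([p1, p2], mapping)
        assert p1.is_decoy and not p2.is_decoy
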