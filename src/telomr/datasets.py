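"""Bundled summary data from a published one-sample MR study.

Genotype distributions, allele frequencies and instrument summary statistics
from a case-control study of leukocyte telomere length and first-ever ischemic
stroke in a Han Chinese population (431 cases, 304 controls; twelve candidate
SNPs, two retained as instruments under the over-dominant model).  Only
group-level numbers are bundled -- the individual-level data are not public --
so these serve as worked examples for the summary-statistic stages and as the
reference panel for the synthetic cohort generator.
"""

from __future__ import annotations

from .genetics import GenotypeCounts
from .linear import SummaryAssociations
from .validate import AssociationResult, InstrumentReport

# (hom_ref, het, hom_alt) genotype counts for the eight candidate SNPs with
# MAF >= 0.05, by group.
CONTROL_GENOTYPE_COUNTS: dict[str, GenotypeCounts] = {
    "rs11125529": GenotypeCounts(202, 92, 10),
    "rs10936599": GenotypeCounts(103, 148, 53),
    "rs7726159": GenotypeCounts(114, 147, 43),
    "rs17653722": GenotypeCounts(220, 76, 8),
    "rs8105767": GenotypeCounts(159, 125, 20),
    "rs409627": GenotypeCounts(129, 145, 30),
    "rs412658": GenotypeCounts(130, 143, 31),
    "rs755017": GenotypeCounts(102, 147, 55),
}

CASE_GENOTYPE_COUNTS: dict[str, GenotypeCounts] = {
    "rs11125529": GenotypeCounts(305, 112, 14),
    "rs10936599": GenotypeCounts(121, 225, 85),
    "rs7726159": GenotypeCounts(155, 195, 81),
    "rs17653722": GenotypeCounts(302, 117, 12),
    "rs8105767": GenotypeCounts(215, 177, 39),
    "rs409627": GenotypeCounts(189, 192, 50),
    "rs412658": GenotypeCounts(188, 190, 53),
    "rs755017": GenotypeCounts(163, 199, 69),
}

# The four candidates excluded by the MAF >= 0.05 filter (control-group MAF).
LOW_MAF_SNPS: dict[str, float] = {
    "rs6772228": 0.000,
    "rs9420907": 0.006,
    "rs3027234": 0.042,
    "rs6028466": 0.002,
}

INSTRUMENTS = ("rs11125529", "rs412658")

# Published over-dominant instrument summaries: control-group mean difference
# in ln telomere length (heterozygote vs both homozygotes) and the all-subject
# odds ratio of ischemic stroke for the heterozygote, each with 95% CI.
INSTRUMENT_MD = {"rs11125529": (-0.108, (-0.204, -0.013)),
                 "rs412658": (-0.089, (-0.176, -0.001))}
INSTRUMENT_MD_P = {"rs11125529": 0.026, "rs412658": 0.049}
INSTRUMENT_OR = {"rs11125529": (0.810, (0.580, 1.120)),
                 "rs412658": (0.890, (0.660, 1.190))}

# Group sizes and headline counts used by the descriptive worked examples.
N_CASES, N_CONTROLS = 431, 304
MALE_CASES, MALE_CONTROLS = 244, 130


def study_summary_associations() -> SummaryAssociations:
    """Per-instrument (beta_x, beta_y) pairs from the published point estimates
    and CIs (SEs recovered as CI width / 3.92); beta_y on the log-OR scale."""
    import numpy as np

    ids = list(INSTRUMENTS)
    bx = [INSTRUMENT_MD[s][0] for s in ids]
    ci_x = [INSTRUMENT_MD[s][1] for s in ids]
    by = [float(np.log(INSTRUMENT_OR[s][0])) for s in ids]
    ci_y = [tuple(np.log(INSTRUMENT_OR[s][1])) for s in ids]
    return SummaryAssociations.from_ci(ids, bx, ci_x, by, ci_y)


def study_candidate_reports() -> list[InstrumentReport]:
    """Instrument reports for the twelve-candidate panel as derivable from the
    published group-level tables.

    The two instruments carry their published exposure associations; exposure
    associations for the remaining typed SNPs are not published, which the
    selection step treats as "association not demonstrated".
    """
    from .genetics import compute_maf, hwe_test
    from .validate import Z95

    reports: list[InstrumentReport] = []
    for snp, maf in LOW_MAF_SNPS.items():
        reports.append(InstrumentReport(snp, maf, None, None))
    for snp, counts in CONTROL_GENOTYPE_COUNTS.items():
        maf = compute_maf(counts)
        hwe_p = hwe_test(counts, method="exact").p_value
        assoc = None
        if snp in INSTRUMENT_MD:
            md, (lo, hi) = INSTRUMENT_MD[snp]
            assoc = AssociationResult(
                effect=md, se=(hi - lo) / (2 * Z95), ci95=(lo, hi),
                p_value=INSTRUMENT_MD_P[snp], n_used=N_CONTROLS,
                model="over-dominant", kind="mean_difference", term=snp,
            )
        reports.append(InstrumentReport(snp, maf, hwe_p, assoc))
    return reports
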