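"""Published reference values for the 30-locus Investigator DIPplex panel
typed in 125 unrelated Bai individuals (Dali, Yunnan, China).

Each row carries the printed per-locus values: DIP- and DIP+ allele
frequencies, observed and expected heterozygosity, Hardy-Weinberg p-value,
typical paternity index, polymorphic information content, power of
exclusion and discrimination power, all to 4 decimal places.  Because the
frequencies are printed at that precision and n=125, the underlying integer
genotype counts are exactly recoverable
(:func:`indelpanel.genotype_io.reconstruct_genotype_counts`).
"""

from __future__ import annotations

from typing import NamedTuple

import numpy as np

from .genotype_io import FrequencyTable, GenotypeCounts, Locus, reconstruct_genotype_counts

__all__ = ["PanelRow", "BAI_PANEL", "bai_loci", "bai_reference_frequencies", "bai_genotype_counts"]

SAMPLE_SIZE = 125


class PanelRow(NamedTuple):
    name: str
    rs_id: str
    p_del: float
    p_ins: float
    ho: float
    he: float
    hwe_p: float
    tpi: float
    pic: float
    pe: float
    dp: float


# name, rs#, DIP-, DIP+, Ho, He, p, TPI, PIC, PE, DP
BAI_PANEL: list[PanelRow] = [
    PanelRow("HLD6", "rs1610905", 0.5200, 0.4800, 0.4640, 0.4992, 0.4054, 0.9328, 0.3746, 0.1579, 0.6403),
    PanelRow("HLD39", "rs17878444", 0.8320, 0.1680, 0.3040, 0.2796, 0.5617, 0.7184, 0.2405, 0.0652, 0.4449),
    PanelRow("HLD40", "rs2307956", 0.3840, 0.6160, 0.4000, 0.4731, 0.0932, 0.8333, 0.3612, 0.1139, 0.6331),
    PanelRow("HLD45", "rs2307959", 0.3920, 0.6080, 0.4640, 0.4767, 0.7441, 0.9328, 0.3631, 0.1579, 0.6177),
    PanelRow("HLD48", "rs28369942", 0.6360, 0.3640, 0.4560, 0.4630, 0.8424, 0.9191, 0.3558, 0.1518, 0.6071),
    PanelRow("HLD56", "rs2308292", 0.4360, 0.5640, 0.3920, 0.4918, 0.0228, 0.8224, 0.3709, 0.1091, 0.6533),
    PanelRow("HLD58", "rs1610937", 0.6160, 0.3840, 0.4800, 0.4731, 0.9107, 0.9615, 0.3612, 0.1706, 0.6075),
    PanelRow("HLD64", "rs1610935", 0.1320, 0.8680, 0.2160, 0.2292, 0.7085, 0.6378, 0.2029, 0.0343, 0.3752),
    PanelRow("HLD67", "rs1305056", 0.3280, 0.6720, 0.4320, 0.4408, 0.8114, 0.8803, 0.3437, 0.1346, 0.5929),
    PanelRow("HLD70", "rs2307652", 0.3560, 0.6440, 0.4560, 0.4585, 0.9219, 0.9191, 0.3534, 0.1518, 0.6026),
    PanelRow("HLD77", "rs1611048", 0.5600, 0.4400, 0.5280, 0.4928, 0.4576, 1.0593, 0.3714, 0.2132, 0.6026),
    PanelRow("HLD81", "rs17879936", 0.1400, 0.8600, 0.1840, 0.2408, 0.1314, 0.6127, 0.2118, 0.0256, 0.3740),
    PanelRow("HLD83", "rs2308072", 0.6200, 0.3800, 0.5520, 0.4712, 0.0772, 1.1161, 0.3602, 0.2372, 0.5661),
    PanelRow("HLD84", "rs3081400", 0.3000, 0.7000, 0.3760, 0.4200, 0.3010, 0.8013, 0.3318, 0.1000, 0.5839),
    PanelRow("HLD88", "rs8190570", 0.4720, 0.5280, 0.5120, 0.4984, 0.7959, 1.0246, 0.3742, 0.1982, 0.6172),
    PanelRow("HLD92", "rs17174476", 0.5360, 0.4640, 0.4480, 0.4974, 0.2504, 0.9058, 0.3737, 0.1459, 0.6444),
    PanelRow("HLD93", "rs2307570", 0.4600, 0.5400, 0.4240, 0.4968, 0.0944, 0.8681, 0.3734, 0.1292, 0.6511),
    PanelRow("HLD97", "rs17238892", 0.6840, 0.3160, 0.3920, 0.4323, 0.3431, 0.8224, 0.3389, 0.1091, 0.5938),
    PanelRow("HLD99", "rs2308163", 0.2000, 0.8000, 0.3040, 0.3200, 0.6790, 0.7184, 0.2688, 0.0652, 0.4854),
    PanelRow("HLD101", "rs2307433", 0.5520, 0.4480, 0.4480, 0.4946, 0.2774, 0.9058, 0.3723, 0.1459, 0.6415),
    PanelRow("HLD111", "rs1305047", 0.8880, 0.1120, 0.1920, 0.1989, 0.8293, 0.6188, 0.1791, 0.0276, 0.3356),
    PanelRow("HLD114", "rs2307581", 0.8160, 0.1840, 0.3200, 0.3003, 0.6521, 0.7353, 0.2552, 0.0721, 0.4667),
    PanelRow("HLD118", "rs16438", 0.1080, 0.8920, 0.1520, 0.1927, 0.2408, 0.5896, 0.1741, 0.0181, 0.3100),
    PanelRow("HLD122", "rs8178524", 0.7600, 0.2400, 0.3680, 0.3648, 0.9679, 0.7911, 0.2983, 0.0956, 0.5297),
    PanelRow("HLD124", "rs6481", 0.4640, 0.5360, 0.4800, 0.4974, 0.6643, 0.9615, 0.3737, 0.1706, 0.6318),
    PanelRow("HLD125", "rs16388", 0.5480, 0.4520, 0.5360, 0.4954, 0.3878, 1.0776, 0.3727, 0.2210, 0.6004),
    PanelRow("HLD128", "rs2307924", 0.7480, 0.2520, 0.3600, 0.3770, 0.6697, 0.7813, 0.3059, 0.0914, 0.5426),
    PanelRow("HLD131", "rs1611001", 0.5720, 0.4280, 0.5680, 0.4896, 0.0875, 1.1574, 0.3698, 0.2542, 0.5737),
    PanelRow("HLD133", "rs2067235", 0.6120, 0.3880, 0.5040, 0.4749, 0.5429, 1.0081, 0.3621, 0.1910, 0.5979),
    PanelRow("HLD136", "rs16363", 0.4880, 0.5120, 0.4480, 0.4997, 0.2297, 0.9058, 0.3749, 0.1459, 0.6467),
]

_BY_NAME = {row.name: row for row in BAI_PANEL}


def bai_loci() -> list[Locus]:
    """The 30 panel loci with their dbSNP identifiers."""
    return [Locus(row.name, row.rs_id) for row in BAI_PANEL]


def bai_reference_frequencies() -> FrequencyTable:
    """Single-population frequency table of the published DIP- frequencies."""
    return FrequencyTable(
        populations=["Bai"],
        loci=bai_loci(),
        p_del=np.array([[row.p_del for row in BAI_PANEL]]),
    )


def bai_genotype_counts() -> dict[str, GenotypeCounts]:
    """Integer genotype counts recovered from each published row."""
    return {
        row.name: reconstruct_genotype_counts(row.p_del, row.ho, SAMPLE_SIZE)
        for row in BAI_PANEL
    }


def panel_row(name: str) -> PanelRow:
    return _BY_NAME[name]
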