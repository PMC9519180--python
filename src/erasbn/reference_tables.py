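"""Published contingency tables from a multicenter ERAS anesthesia cohort.

A published three-hospital study of 1,827 benign-gynecological-tumor
patients applied this package's protocol to 18 anesthesia-decision
indicators with length of stay (LOS) and total cost (TC) as outcomes.  Its
raw records are access-restricted, but its printed tables are complete
enough to re-derive every reported statistic: the grade-by-group counts for
each indicator, the single-indicator pool breakdowns (pools of 957/558 cases
for LOS and 840/681 for TC), and the cumulative multi-indicator 2x2 tables.

This module stores those printed counts verbatim so the test suite and the
reproduction script can recompute the reported p-values, proportions and
significant-indicator counts from first principles.  ``printed_p`` values
are the p-values as published, kept only for comparison — nothing in the
package ever returns them as results.
"""

from __future__ import annotations

from dataclasses import dataclass

__all__ = [
    "PublishedTable",
    "COHORT_SIZE",
    "LOS_BELOW_MEAN",
    "TC_BELOW_MEAN",
    "GROUP_TABLES_LOS",
    "GROUP_TABLES_TC",
    "BREAKDOWN_LOS",
    "BREAKDOWN_TC",
    "CUMULATIVE_LOS",
    "CUMULATIVE_TC",
    "LOS_POOL_SIZES",
    "TC_POOL_SIZES",
]


@dataclass(frozen=True)
class PublishedTable:
    """One printed grade-by-group count table with its published p-value."""

    indicator: str
    grades: tuple[str, ...]
    counts: tuple[tuple[int, int], ...]  # one (group0, group1) pair per grade
    printed_p: float | None = None


COHORT_SIZE = 1827
LOS_BELOW_MEAN = 1143  # LOS < 4.546 d
TC_BELOW_MEAN = 987  # TC < 17,548.3355 Yuan

# Grade counts by outcome group over the full cohort (mean-split LOS / TC).
# printed_p = 0.0 stands for the published "0.000" (i.e. p < 0.001).
GROUP_TABLES_LOS: tuple[PublishedTable, ...] = (
    PublishedTable("urine_ratio", ("Low", "High"),
                   ((333, 267), (810, 411)), 0.0),
    PublishedTable("dexamethasone", ("N", "Y"),
                   ((852, 528), (291, 153)), 0.150),
    PublishedTable("sevoflurane", ("N", "Y"),
                   ((921, 561), (222, 120)), 0.340),
    PublishedTable("propofol", ("N", "Y"),
                   ((99, 45), (1044, 636)), 0.116),
    PublishedTable("crystalloid_colloid_ratio", ("Low", "High", "Less"),
                   ((444, 207), (186, 144), (513, 330)), 0.0),
    PublishedTable("transfusion_hb_6_9", ("0", "1", "2"),
                   ((69, 45), (18, 18), (1095, 618)), 0.183),
    PublishedTable("dexmedetomidine", ("N", "Y"),
                   ((249, 114), (894, 567)), 0.009),
    PublishedTable("sbp", ("Low", "Normal", "High"),
                   ((183, 144), (918, 516), (39, 18)), 0.017),
    PublishedTable("dbp", ("Low", "Normal", "High"),
                   ((171, 132), (924, 507), (48, 42)), 0.005),
    PublishedTable("mbp", ("Low", "Normal", "High"),
                   ((105, 96), (990, 546), (45, 36)), 0.001),
    PublishedTable("etco2", ("0", "1", "2"),
                   ((693, 360), (450, 318), (0, 3)), 0.0),
    PublishedTable("positive_balance", ("0", "1", "2", "3"),
                   ((231, 87), (729, 468), (168, 108), (15, 18)), 0.0),
    PublishedTable("myocardial_nutrition", ("N", "Y"),
                   ((1038, 603), (105, 78)), 0.119),
    PublishedTable("hemostatic", ("N", "Y"),
                   ((735, 450), (408, 231)), 0.442),
    PublishedTable("nerve_block_analgesia", ("N", "Y"),
                   ((687, 366), (456, 315)), 0.008),
    PublishedTable("opioid_dominant_analgesia", ("N", "Y"),
                   ((1119, 648), (24, 33)), 0.001),
    PublishedTable("nsaid_analgesia", ("N", "Y"),
                   ((618, 405), (525, 276)), 0.025),
    PublishedTable("muscle_relaxant_antagonist", ("N", "Y"),
                   ((273, 162), (870, 519)), 0.963),
)

GROUP_TABLES_TC: tuple[PublishedTable, ...] = (
    PublishedTable("urine_ratio", ("Low", "High"),
                   ((321, 282), (666, 555)), 0.597),
    PublishedTable("dexamethasone", ("N", "Y"),
                   ((663, 717), (324, 123)), 0.0),
    PublishedTable("sevoflurane", ("N", "Y"),
                   ((801, 684), (186, 156)), 0.881),
    PublishedTable("propofol", ("N", "Y"),
                   ((78, 66), (909, 774)), 0.971),
    PublishedTable("crystalloid_colloid_ratio", ("Low", "High", "Less"),
                   ((429, 225), (138, 192), (420, 423)), 0.0),
    PublishedTable("transfusion_hb_6_9", ("0", "1", "2"),
                   ((15, 99), (0, 36), (972, 705)), 0.0),
    PublishedTable("dexmedetomidine", ("N", "Y"),
                   ((309, 54), (678, 786)), 0.0),
    PublishedTable("sbp", ("Low", "Normal", "High"),
                   ((207, 123), (765, 669), (12, 45)), 0.0),
    PublishedTable("dbp", ("Low", "Normal", "High"),
                   ((168, 135), (789, 645), (30, 60)), 0.0),
    PublishedTable("mbp", ("Low", "Normal", "High"),
                   ((126, 75), (837, 702), (21, 60)), 0.0),
    PublishedTable("etco2", ("0", "1", "2"),
                   ((627, 429), (360, 408), (0, 3)), 0.0),
    PublishedTable("positive_balance", ("0", "1", "2", "3"),
                   ((195, 123), (636, 564), (147, 129), (9, 24)), 0.001),
    PublishedTable("myocardial_nutrition", ("N", "Y"),
                   ((960, 684), (27, 156)), 0.0),
    PublishedTable("hemostatic", ("N", "Y"),
                   ((597, 588), (390, 252)), 0.0),
    PublishedTable("nerve_block_analgesia", ("N", "Y"),
                   ((504, 549), (483, 291)), 0.0),
    PublishedTable("opioid_dominant_analgesia", ("N", "Y"),
                   ((966, 804), (21, 36)), 0.008),
    PublishedTable("nsaid_analgesia", ("N", "Y"),
                   ((369, 654), (618, 186)), 0.0),
    PublishedTable("muscle_relaxant_antagonist", ("N", "Y"),
                   ((264, 171), (723, 669)), 0.001),
)

LOS_POOL_SIZES = (957, 558)  # retained cases per LOS state
TC_POOL_SIZES = (840, 681)

# Single-indicator breakdowns of the retained pools (selected rows with a
# reproducible printed p-value; counts are (state-0 pool, state-1 pool)).
BREAKDOWN_LOS: tuple[PublishedTable, ...] = (
    PublishedTable("urine_ratio", ("Low", "High"),
                   ((315, 252), (642, 306)), 0.000002),
    PublishedTable("crystalloid_colloid_ratio", ("Low", "High", "Less"),
                   ((381, 168), (171, 132), (405, 258)), 0.000289),
    PublishedTable("positive_balance", ("0", "1", "2", "3"),
                   ((216, 81), (570, 363), (156, 96), (15, 18)), 0.000437),
    PublishedTable("opioid_dominant_analgesia", ("N", "Y"),
                   ((933, 525), (24, 33)), 0.000778),
)

BREAKDOWN_TC: tuple[PublishedTable, ...] = (
    PublishedTable("dexmedetomidine", ("N", "Y"),
                   ((273, 51), (567, 630)), 2.2441e-32),
    PublishedTable("transfusion_hb_6_9", ("0", "1", "2"),
                   ((15, 99), (0, 33), (825, 549)), 4.4001e-30),
    PublishedTable("nsaid_analgesia", ("N", "Y"),
                   ((279, 510), (561, 171)), 7.4736e-59),
    PublishedTable("myocardial_nutrition", ("N", "Y"),
                   ((813, 525), (27, 156)), 8.0189e-32),
)

# Cumulative combination steps: (indicator, grade, state-0 matches,
# state-1 matches, published p).  Match counts are within the pools above.
CUMULATIVE_LOS: tuple[tuple[str, str, int, int, float | None], ...] = (
    ("urine_ratio", "High", 642, 306, 0.000002),
    ("etco2", "0", 411, 171, 0.000002),
    ("crystalloid_colloid_ratio", "Less", 165, 78, 0.095058),
    ("mbp", "Normal", 147, 45, 0.000038),
    ("positive_balance", "1", 105, 39, 0.010791),
    ("opioid_dominant_analgesia", "N", 105, 36, 0.003489),
    ("dbp", "Normal", 84, 33, 0.044027),
    ("sbp", "Normal", 63, 24, 0.065549),
    ("nerve_block_analgesia", "N", 42, 12, 0.023422),
    ("nsaid_analgesia", "N", 21, 6, 0.1441),
    ("myocardial_nutrition", "N", 15, 3, 0.074374),
    ("dexmedetomidine", "Y", 9, 3, 0.3936),
    ("propofol", "Y", 6, 3, 0.827249),
    ("transfusion_hb_6_9", "2", 3, 3, 0.502826),
    ("dexamethasone", "N", 3, 3, 0.502826),
    ("sevoflurane", "N", 3, 0, 0.30156),
    ("muscle_relaxant_antagonist", "Y", 0, 0, None),
    ("hemostatic", "N", 0, 0, None),
)

CUMULATIVE_TC: tuple[tuple[str, str, int, int, float | None], ...] = (
    ("nsaid_analgesia", "Y", 561, 171, 7.47e-59),
    ("dexmedetomidine", "Y", 384, 132, 4.03e-27),
    ("myocardial_nutrition", "N", 381, 105, 1.37e-35),
    ("transfusion_hb_6_9", "2", 378, 99, 3.87e-37),
    ("dexamethasone", "N", 195, 57, 9.72e-15),
    ("crystalloid_colloid_ratio", "Low", 99, 6, 7.31e-17),
    ("etco2", "0", 69, 0, 1.93e-14),
    ("nerve_block_analgesia", "Y", 30, 0, 6.32e-07),
    ("sbp", "Normal", 18, 0, 1.22e-04),
    ("mbp", "Normal", 18, 0, 1.22e-04),
    ("hemostatic", "N", 9, 0, 0.017642),
    ("dbp", "Normal", 9, 0, 0.017642),
    ("positive_balance", "1", 6, 0, 0.072087),
    ("muscle_relaxant_antagonist", "Y", 6, 0, 0.072087),
    ("opioid_dominant_analgesia", "N", 6, 0, 0.072087),
    ("urine_ratio", "High", 3, 0, 0.327101),
    ("sevoflurane", "N", 3, 0, 0.327101),
    ("propofol", "Y", 3, 0, 0.327101),
)
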