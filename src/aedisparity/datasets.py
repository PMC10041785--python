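"""Published example tables bundled as ready-made inputs.

Two worked examples from the FAERS liver-toxicity analysis:

* ``analgesics_sex()`` — the by-drug family of the 12 analgesics that
  pass preprocessing for the composite liver-toxicity event, split by
  sex (group 1 = male). Shared margins: 47830 male / 53078 female
  liver-toxicity reports.
* ``liver_tox_by_ae_hits()`` — the 24 drugs flagged by the LR test with
  Max-Stat adjustment in the by-AE orientation (context = drug, unit =
  liver toxicity vs the drug's other events), as individual tables.

Cell order in the raw tuples follows the published layout:
(no-drug group 1, no-drug group 2, drug group 1, drug group 2) for the
analgesics, and (no-event male, no-event female, event male, event
female) for the by-AE tables.
"""

from __future__ import annotations

from .tables import HostTable, TableFamily

__all__ = ["analgesics_sex", "liver_tox_by_ae_hits", "ANALGESICS_SEX_CELLS"]

# drug -> (b1, b2, a1, a2): unexposed male/female, exposed male/female
ANALGESICS_SEX_CELLS: dict[str, tuple[int, int, int, int]] = {
    "acetaminophen": (46798, 51289, 1032, 1789),
    "aspirin": (47695, 52984, 135, 94),
    "ibuprofen": (47566, 52706, 264, 372),
    "meloxicam": (47818, 53044, 12, 34),
    "etodolac": (47821, 53053, 9, 25),
    "indomethacin": (47820, 53053, 10, 25),
    "ketoprofen": (47821, 53073, 9, 5),
    "diclofenac": (47625, 52822, 205, 256),
    "ketorolac": (47824, 53067, 6, 11),
    "piroxicam": (47821, 53063, 9, 15),
    "nabumetone": (47825, 53069, 5, 9),
    "naproxen": (47750, 52982, 80, 96),
}

# drug -> (no liver tox male, no liver tox female, liver tox male, liver tox female)
LIVER_TOX_BY_AE_CELLS: dict[str, tuple[int, int, int, int]] = {
    "leuprolide": (4405, 5341, 133, 24),
    "isotretinoin": (6044, 7457, 423, 253),
    "etanercept": (43723, 124146, 614, 1168),
    "rosuvastatin": (8153, 11178, 565, 498),
    "fingolimod": (2330, 9148, 172, 338),
    "azithromycin": (1653, 2633, 147, 101),
    "esomeprazole": (7125, 16566, 180, 234),
    "adalimumab": (42601, 96825, 658, 1135),
    "cyclosporine": (4716, 5530, 489, 385),
    "amlodipine": (4776, 7825, 156, 134),
    "metformin": (4896, 6604, 390, 346),
    "sorafenib": (5250, 2100, 1107, 299),
    "aripiprazole": (5592, 7428, 134, 91),
    "doxorubicin": (1349, 2671, 120, 125),
    "propranolol": (659, 1113, 48, 26),
    "amoxicillin-clavulanate": (1287, 1708, 417, 367),
    "insulin glargine": (6233, 8495, 87, 55),
    "clarithromycin": (1751, 2674, 190, 174),
    "doxycycline": (770, 1446, 92, 84),
    "valsartan": (3883, 6148, 155, 146),
    "ranitidine": (1750, 2945, 75, 58),
    "topotecan": (364, 717, 42, 27),
    "fluvastatin": (348, 305, 80, 151),
    "peginterferon alfa-2b": (4750, 4086, 286, 163),
}


def analgesics_sex() -> TableFamily:
    """The 12-analgesic by-drug family for liver toxicity, split by sex."""
    tables = [
        HostTable("by_drug", drug, "liver toxicity", a1, a2, b1, b2)
        for drug, (b1, b2, a1, a2) in ANALGESICS_SEX_CELLS.items()
    ]
    return TableFamily(tables)


def liver_tox_by_ae_hits() -> list[HostTable]:
    """By-AE liver-toxicity tables for the 24 published LR hits.

    Each table fixes one drug; the unit is the liver-toxicity event and
    the margins are the drug's total male/female report counts. These are
    separate families (one per drug), so they are returned as tables, not
    one family.
    """
    return [
        HostTable("by_ae", "liver toxicity", drug, a1, a2, b1, b2)
        for drug, (b1, b2, a1, a2) in LIVER_TOX_BY_AE_CELLS.items()
    ]
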