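"""Published referral-area figures for the packaged reference run.

These constants are the region-level census and surgical-registry
figures for the Lisbon tertiary-centre referral area (41 municipalities,
Portuguese censuses 2001/2011/2021; institutional SAVR registry decade
totals for patients >=65).  They let the full pipeline run end to end
without any external data file.
"""

from __future__ import annotations

from .demand import SurgeryDecade

#: 2021 census, whole referral region
TOTAL_POP_2021 = 2_319_319
POP_65_PLUS_2021 = 535_894

#: observed annual geometric growth rates, percent/year
RATE_TOTAL_2001_2011 = 0.49
RATE_TOTAL_2011_2021 = 0.19
RATE_65_2001_2011 = 1.69
RATE_65_2011_2021 = 1.40

#: per-decade decrements implied by the observed inter-decade slow-down
DECREMENT_TOTAL = 0.30  # 0.49 - 0.19
DECREMENT_65 = 0.29     # 1.69 - 1.40

#: registry decade totals: SAVR for aortic stenosis, patients >=65
SURGERIES_2001_2011 = SurgeryDecade(2001, 2011, 1538)
SURGERIES_2011_2021 = SurgeryDecade(2011, 2021, 2424)

BASE_YEAR = 2021
HORIZON = 2041

BASE_RATES = {"total": RATE_TOTAL_2011_2021, "age_65_plus": RATE_65_2011_2021}
DECREMENTS = {"total": DECREMENT_TOTAL, "age_65_plus": DECREMENT_65}
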