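"""Feasibility and acceptability rates from the participant-flow ledger.

Builds the per-patient ledger preset encoding the pilot's participant flow
(1037 screened down to 90 randomised) and tabulates every pre-specified
feasibility outcome with its raw numerator/denominator.
"""

from briskwalk.feasibility import feasibility_report
from briskwalk.synthetic import paper_ledger

ledger = paper_ledger()
report = feasibility_report(ledger)
print(report.to_string(index=False))
# 'percentage' is rounded half-up to integer percent; 'percentage_1dp' to
# one decimal.  Each rate can be re-derived from its numerator/denominator;
# an empty denominator would be reported as undefined, never as 0%.
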