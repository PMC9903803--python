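"""Published sibling-recurrence estimates used as worked-example inputs.

These are odds ratios (with 95% CIs) for diagnoses among siblings of index
cases versus age- and sex-matched population controls, as reported by a
national-registry sibling-recurrence study of ASD and intellectual
disability.  They serve as inputs to the OR-comparison machinery (the log-OR
standard errors are reconstructed from the printed intervals), not as
outputs of this package.

Keys are (index-case sex, index-case diagnosis group, sibling outcome);
values are (OR, CI low, CI high).
"""

from __future__ import annotations

__all__ = ["REPORTED_SIBLING_ORS"]

REPORTED_SIBLING_ORS: dict[tuple[str, str, str], tuple[float, float, float]] = {
    ("F", "ASDnoID", "ASDnoID"): (7.19, 5.09, 10.09),
    ("M", "ASDnoID", "ASDnoID"): (3.76, 3.10, 4.54),
    ("F", "IDnoASD", "ASDandID"): (2.00, 0.12, 32.07),
    ("M", "IDnoASD", "ASDandID"): (6.02, 0.63, 57.95),
    ("F", "IDnoASD", "ASDnoID"): (2.01, 0.80, 5.12),
    ("M", "IDnoASD", "ASDnoID"): (1.49, 0.79, 2.80),
}
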