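"""Unit conversion constants.

The package works internally in a mm–MPa–s system; pressures are accepted in
mmHg at the interfaces and converted once with the factors below.
"""

#: 1 mmHg in MPa.
MMHG_TO_MPA = 1.333224e-4

#: 1 mmHg in kPa (used where wall stress is reported in kPa).
MMHG_TO_KPA = 0.1333224
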