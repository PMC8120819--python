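"""Sweetness equivalence of fruit pulp, and scaling by an expression ratio.

Neoculin is ~550x sweeter than sucrose, and the sweet species' fruit holds
about 1.3 mg of it per gram of fresh pulp. The product gives the sucrose
equivalent of one gram of pulp; dividing the content by the 60-fold lower
transcript level seen in the non-sweet relative predicts how little neoculin
(and hence sweetness) that species' fruit can muster.
"""

from curculigo import scale_by_expression_ratio, sucrose_equivalent
from curculigo.sweetness import QpcrSample, delta_delta_ct, round_sig

content = 1.3   # mg neoculin per g fresh pulp
factor = 550    # fold sweetness vs sucrose

equivalent = sucrose_equivalent(content, factor)
print(f"sweet species: {content} mg/g x {factor} = {equivalent:.6g} mg sucrose per g pulp")

scaled = scale_by_expression_ratio(content, 60, factor)
print(
    f"relative at 1/60 expression: {round_sig(scaled.content_mg_per_g * 1000):g} ug/g "
    f"neoculin -> {round_sig(scaled.sucrose_equivalent_mg_per_g):g} mg sucrose per g"
)

# qPCR side: a sample whose target is 3 cycles 'earlier' (after reference-gene
# normalisation) than the calibrator is 2^3 = 8-fold more expressed.
fold = delta_delta_ct(QpcrSample(20, 18), QpcrSample(24, 19))
print(f"ddCt example: fold change = {fold:g}")
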