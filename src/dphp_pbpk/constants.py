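"""Chemical reference constants.

Molecular weights (g/mol) for the parent diester, the monoester and the
second-order metabolites, from standard chemical references (monoisotopic
formulae DPHP C28H46O4, MPHP C18H26O4, OH-MPHP C18H26O5, cx-MPHP C18H24O6,
oxo-MPHP C18H24O5).  These sit outside the model arithmetic proper and may
be overridden through configuration.
"""

MW_DPHP = 446.66
MW_MPHP = 306.40
MW_OH_MPHP = 322.40
MW_CX_MPHP = 336.38
MW_OXO_MPHP = 320.38

#: microsomal incubation volume per mg protein (mL/mg); the depletion assays
#: used 0.5 mg microsomal protein per mL of incubation medium.
INCUBATION_ML_PER_MG = 2.0

#: gastric-emptying coefficient relaxation time (h); the time-varying
#: first-order coefficient decays from k_max toward k_min with this constant.
TAU_GASTRIC_DEFAULT = 1.0
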