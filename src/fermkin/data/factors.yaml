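# Factor definitions and term-selection variants of the reference
# biosurfactant optimization design (five factors, three levels each).
factors:
  - {name: X1, low: 5, high: 7}        # pH
  - {name: X2, low: 25, high: 35}      # temperature, degC
  - {name: X3, low: 4.5, high: 6.5}    # waste frying oil, g
  - {name: X4, low: 150, high: 250}    # agitation rate, rpm
  - {name: X5, low: 5, high: 9}        # incubation time, day

# Selected-term sets as reported for the reference design.  The source
# report is internally inconsistent about two interaction labels, so
# both readings ship: `text_variant` follows the narrative (and the
# ANOVA table), `table_variant` follows the parameter-estimate table
# literally.
term_variants:
  text_variant: [Intercept, X1, X2, X2*X4, X3*X5, X4^2, X5^2]
  table_variant: [Intercept, X1, X2, X4*X5, X3*X5, X4^2, X5^2]

# The full initial model the design was built for.
initial_terms: [Intercept, X1, X2, X3, X4, X5,
                X1*X2, X1*X3, X2*X3, X1*X4, X2*X4, X3*X4,
                X1*X5, X2*X5, X3*X5, X4*X5,
                X1^2, X2^2, X3^2, X4^2, X5^2]
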