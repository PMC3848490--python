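# Default autoimmune / chronic-inflammatory trait whitelist.
# Matching is case-insensitive with whitespace normalization; extend or
# replace via --traits on the command line.
traits:
  - ulcerative colitis
  - crohn's disease
  - "crohn’s disease"
  - inflammatory bowel disease
  - inflammatory bowel disease, early onset
  - type 1 diabetes
  - multiple sclerosis
  - primary biliary cirrhosis
  - psoriasis
  - asthma
  - rheumatoid arthritis
  - celiac disease
  - systemic lupus erythematosus
  - ankylosing spondylitis
  - c-reactive protein
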