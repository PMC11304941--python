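"""Shared allele, phase-state and origin codes.

Kept in one module so that I/O, phasing and origin inference agree on the
integer encodings without importing each other.
"""

# Allele codes (PLINK flat-file convention used throughout).
ALLELE_MISSING = 0
ALLELE_MAJOR = 1
ALLELE_MINOR = 2

# Per-locus phase states. RESOLVED alleles come straight from Mendelian
# segregation; IMPUTED alleles were filled in from an inferred haplotype
# origin. TH/MD/ME carry no allele value.
ST_RESOLVED = 0
ST_TH = 1        # all trio members heterozygous
ST_MD = 2        # missing data somewhere in the trio
ST_ME = 3        # Mendelian error
ST_IMPUTED = 4

STATE_TOKENS = {ST_TH: "TH", ST_MD: "MD", ST_ME: "ME"}
UNRESOLVED_STATES = (ST_TH, ST_MD, ST_ME)

# Grandparental origin codes for one homolog.
OR_NONE = 0      # noninformative ("*"): transmitting parent homozygous,
                 # parent phase incomplete, or origin filtered out
OR_P = 1         # grandpaternal
OR_M = 2         # grandmaternal
OR_Q = 3         # offspring allele unphased (TH or MD): "?"
OR_BANG = 4      # offspring allele flagged as Mendelian error: "!"

ORIGIN_CHARS = {OR_NONE: "*", OR_P: "P", OR_M: "M", OR_Q: "?", OR_BANG: "!"}
CHAR_ORIGINS = {v: k for k, v in ORIGIN_CHARS.items()}

HOMOLOGS = ("paternal", "maternal")

# Option names mirror the reference tool's argument vocabulary.
IMP_MODES = ("imputeNot", "imputeTHonly", "imputeAll")
COR_MODES = ("correctNot", "correctFalseHom", "reImpute", "correctAll")

CO = "CO"
GC = "GC"
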