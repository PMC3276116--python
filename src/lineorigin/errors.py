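"""Exception hierarchy.

``InputError`` covers everything a user can fix in their input files
(malformed maps, broken pedigrees, inconsistent genotypes); the CLI maps it
to exit code 2.  Anything else is an internal failure (exit code 3).
"""


class InputError(ValueError):
    """Invalid or inconsistent user input."""


class MapError(InputError):
    """Invalid genetic map: negative distances, unordered or unresolvable positions."""


class PedigreeError(InputError):
    """Pedigree violates the three-generation line-cross structure."""


class GenotypeError(InputError):
    """Genotype data inconsistent with the map or pedigree."""
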