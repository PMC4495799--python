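"""Exception hierarchy.

``InputError`` maps to CLI exit code 2, ``ClassifierFormatError`` to 3.
"""


class MethclassError(Exception):
    """Base class for all package errors."""


class InputError(MethclassError):
    """Malformed or inconsistent user input (files, labels, config)."""


class ImputationError(MethclassError):
    """kNN imputation cannot proceed (e.g. too few usable neighbor probes)."""


class ClassifierFormatError(MethclassError):
    """Serialized classifier is corrupted or has an incompatible version."""
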