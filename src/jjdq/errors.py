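"""Exception hierarchy for extract parsing, auditing, cleaning and generation."""


class JJDQError(Exception):
    """Base class for all package errors."""


class SchemaError(JJDQError):
    """CSV header does not match the documented extract schema."""


class UniquenessError(JJDQError):
    """Duplicate (case_id, extraction_phase) within one extract."""


class EmptyExtractError(JJDQError):
    """An operation requiring at least one case received an empty extract."""


class PolicyError(JJDQError):
    """A resolution policy names a strategy outside the rule's menu, or lacks one."""


class ConfigError(JJDQError):
    """Invalid synthetic-generator configuration; message names the offending fields."""


class StructuralError(JJDQError):
    """Pre/post report inputs disagree structurally (e.g. mismatched CMS sets)."""


class InjectionError(JJDQError):
    """Requested corruption cannot be applied (rule/scenario mismatch or masked fields)."""
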