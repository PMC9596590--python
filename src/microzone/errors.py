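"""Exception types shared across the package."""


class ConfigurationError(ValueError):
    """A parameter or config entry violates its documented constraint."""


class DispatchError(RuntimeError):
    """A step rule was invoked outside its domain (caller routing bug)."""


class LayoutError(ValueError):
    """A synapse-group layout is inconsistent (e.g. an empty group)."""


class IntegrityError(RuntimeError):
    """A replayed schedule failed to reproduce its stored trajectory."""
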