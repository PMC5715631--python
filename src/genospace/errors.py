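"""Exception hierarchy shared by all genospace modules."""


class GenospaceError(Exception):
    """Base class for all errors raised by genospace."""


class FormatError(GenospaceError):
    """A region or metadata file could not be parsed.

    Carries the offending path and 1-based line number where available.
    """

    def __init__(self, message, path=None, line=None):
        prefix = ""
        if path is not None:
            prefix = f"{path}:"
            if line is not None:
                prefix += f"{line}:"
            prefix += " "
        super().__init__(prefix + message)
        self.path = path
        self.line = line


class SpaceError(GenospaceError):
    """Invalid construction or use of a genometric space."""


class TransitionError(GenospaceError):
    """A transformation was given parameters invalid for its input space."""


class ClusteringError(GenospaceError):
    """Clustering, cutting or the elbow heuristic received invalid input."""


class InferenceError(GenospaceError):
    """A statistical routine received degenerate input."""


class SessionError(GenospaceError):
    """A saved exploration session could not be read or written."""
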