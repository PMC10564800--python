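"""Exception hierarchy for phyclus.

Every structural precondition of the calculus maps to its own exception so
callers can distinguish, e.g., an attempt to contract a shortcut (which would
create a directed cycle) from a merely unknown arc.
"""


class PhyclusError(Exception):
    """Base class for all phyclus errors."""


# --- network construction / lookup -------------------------------------------
class MultipleRoots(PhyclusError):
    """More than one vertex of indegree 0."""


class CyclicGraph(PhyclusError):
    """The arc set contains a directed cycle."""


class UnreachableVertex(PhyclusError):
    """Some vertex is not reachable from the root."""


class LeafLabelMismatch(PhyclusError):
    """Leaf labels do not form a bijection onto the outdegree-0 vertices."""


class UnknownVertex(PhyclusError):
    pass


class UnknownArc(PhyclusError):
    pass


class UnknownLeaf(PhyclusError):
    pass


class EmptyQuery(PhyclusError):
    pass


# --- clustering systems -------------------------------------------------------
class InvalidClusteringSystem(PhyclusError):
    """Violation of the clustering-system axioms (no empty set, X and all
    singletons present)."""


class NotSubsetOfGroundSet(PhyclusError):
    pass


class NotACluster(PhyclusError):
    pass


class NotClosedForTop(PhyclusError):
    """Top(C) for a cluster without overlap-witnesses needs a unique
    inclusion-minimal strict superset, which only closedness guarantees."""


class GroundSetTooLarge(PhyclusError):
    """Exhaustive decision procedure refused: ground set too large."""


class GroundSetTooLargeWithoutL(GroundSetTooLarge):
    """Pre-pyramidality without property (L) is decided by exhaustive order
    search, which is only permitted for small ground sets."""


# --- rewrites -----------------------------------------------------------------
class ShortcutContraction(PhyclusError):
    """Contracting a shortcut would create a directed cycle."""


class NotAShortcut(PhyclusError):
    pass


class PccViolation(PhyclusError):
    pass


class NotSemiRegular(PhyclusError):
    pass


class MultisetMismatch(PhyclusError):
    pass


# --- level-1 ------------------------------------------------------------------
class PreconditionViolated(PhyclusError):
    pass


class HybridIndegreeTooHigh(PhyclusError):
    pass


class NotLevel1(PhyclusError):
    pass


# --- io / generation ----------------------------------------------------------
class ParseError(PhyclusError):
    def __init__(self, message, line=None):
        if line is not None:
            message = f"line {line}: {message}"
        super().__init__(message)
        self.line = line


class UnmatchedHybridTag(ParseError):
    def __init__(self, message):
        super().__init__(message)


class InfeasibleConfig(PhyclusError):
    pass


class BadK(PhyclusError):
    pass


class InstanceTooLarge(PhyclusError):
    pass
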