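"""Global numeric options.

A single switch, ``paper_compat``, controls whether confidence intervals use
the exact Student-t quantile for their multiplier (the default) or the
round number 2.0 that back-of-the-envelope error bars traditionally use for
95% limits.  Worked examples in the primary literature for these metrics
often print 2.0; the exact quantile is the statistically correct choice.
"""

from __future__ import annotations

import contextlib
from typing import Iterator

_PAPER_COMPAT = False


def set_paper_compat(enabled: bool) -> None:
    """Globally enable/disable the 2.0-multiplier convention."""
    global _PAPER_COMPAT
    _PAPER_COMPAT = bool(enabled)


def get_paper_compat() -> bool:
    return _PAPER_COMPAT


@contextlib.contextmanager
def paper_compat(enabled: bool = True) -> Iterator[None]:
    """Context manager scoping the 2.0-multiplier convention."""
    global _PAPER_COMPAT
    previous = _PAPER_COMPAT
    _PAPER_COMPAT = bool(enabled)
    try:
        yield
    finally:
        _PAPER_COMPAT = previous
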