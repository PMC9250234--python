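"""Small shared helpers: chromosome ordering and logging."""

from __future__ import annotations

import logging


def get_logger(name: str) -> logging.Logger:
    return logging.getLogger(f"locogwas.{name}")


def chrom_sort_key(label: str):
    """Order chromosome labels numerically where possible ("2" < "10"),
    falling back to lexicographic order for scaffold/contig names, which
    sort after all numeric chromosomes."""
    try:
        return (0, int(label), "")
    except (TypeError, ValueError):
        return (1, 0, str(label))
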