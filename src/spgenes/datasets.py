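"""Packaged reference data."""

from __future__ import annotations

from importlib import resources

__all__ = ["amd_seed_genes", "amd_seed_path"]


def amd_seed_path():
    """Path-like handle to the packaged AMD seed-gene list."""
    return resources.files(__package__) / "data" / "amd_seed_genes.txt"


def amd_seed_genes() -> list[str]:
    """The 36 curated age-related macular degeneration seed genes."""
    text = amd_seed_path().read_text()
    return [
        line.strip()
        for line in text.splitlines()
        if line.strip() and not line.lstrip().startswith("#")
    ]
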