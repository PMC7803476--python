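"""Access to the bundled, user-editable data files.

Every lexicon famhx ships (stop set, kinship lexicon, composition table,
complex rules, disease dictionary, living-status and negation terms,
wordpiece vocabulary) is a plain newline-delimited text or TSV file under
``famhx/data`` so deployments can replace them without touching code.
"""

from __future__ import annotations

from importlib import resources


def read_data_text(name: str) -> str:
    return resources.files("famhx.data").joinpath(name).read_text(encoding="utf-8")


def load_terms(name: str, lowercase: bool = True) -> list[str]:
    """Load a newline-delimited term file, skipping blanks and ``#`` comments."""
    out = []
    for raw in read_data_text(name).splitlines():
        line = raw.strip()
        if not line or line.startswith("#"):
            continue
        out.append(line.lower() if lowercase else line)
    return out


def load_term_set(name: str, lowercase: bool = True) -> set[str]:
    return set(load_terms(name, lowercase=lowercase))


def load_tsv(name: str) -> list[list[str]]:
    rows = []
    for raw in read_data_text(name).splitlines():
        if not raw.strip() or raw.startswith("#"):
            continue
        rows.append([field.strip() for field in raw.split("\t")])
    return rows
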