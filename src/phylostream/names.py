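"""Unique name shortening shared by the PHYLIP and NEXUS writers.

Formats with length-limited or uniqueness-requiring labels force writers to
edit them.  Unlike plain truncation, the scheme here guarantees that all
written names stay pairwise distinct even when the originals differ only
beyond the cut-off position, and reports every edit through a translation
map so the application can restore the original labels.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .events import WriteError


@dataclass
class NameTranslationMap:
    """Ordered mapping original label -> written label.

    ``touched`` is the subset of originals whose written form differs.
    Because originals may repeat (duplicate input labels), entries are kept
    positionally in ``pairs`` as well.
    """

    pairs: list[tuple[str, str]] = field(default_factory=list)

    @property
    def entries(self) -> dict[str, str]:
        return dict(self.pairs)

    @property
    def touched(self) -> set[str]:
        return {old for old, new in self.pairs if old != new}

    def written(self) -> list[str]:
        return [new for _, new in self.pairs]

    def inverse(self) -> dict[str, str]:
        return {new: old for old, new in self.pairs}


def shorten_names_unique(names: list[str], max_len: int) -> NameTranslationMap:
    """Shorten ``names`` to at most ``max_len`` characters, keeping them
    pairwise distinct.

    Names whose ``max_len``-truncations are already unique are plainly
    truncated.  Colliding names are disambiguated deterministically: the
    name is truncated to ``max_len - k`` and a zero-padded decimal counter
    of width ``k`` is appended, with the smallest ``k`` that resolves all
    collisions and counters assigned in input order.

    Raises :class:`WriteError` (CAPACITY_EXCEEDED) when more names collide
    than the counter scheme can distinguish at ``max_len``.
    """
    if max_len <= 0:
        raise ValueError("max_len must be positive")
    truncs = [name[:max_len] for name in names]
    counts: dict[str, int] = {}
    for t in truncs:
        counts[t] = counts.get(t, 0) + 1

    if all(c == 1 for c in counts.values()):
        return NameTranslationMap(list(zip(names, truncs)))

    unique_truncs = {t for t, c in counts.items() if c == 1}

    for k in range(1, max_len + 1):
        used: set[str] = set(unique_truncs)
        written: list[str] = []
        next_counter: dict[str, int] = {}
        limit = 10 ** k
        ok = True
        for name, t in zip(names, truncs):
            if t in unique_truncs:
                written.append(t)
                continue
            prefix = name[: max_len - k]
            c = next_counter.get(prefix, 1)
            while c < limit and (prefix + str(c).zfill(k)) in used:
                c += 1
            if c >= limit:
                ok = False
                break
            candidate = prefix + str(c).zfill(k)
            next_counter[prefix] = c + 1
            used.add(candidate)
            written.append(candidate)
        if ok:
            return NameTranslationMap(list(zip(names, written)))

    raise WriteError(
        f"cannot make {len(names)} names unique within {max_len} characters",
        code="CAPACITY_EXCEEDED")


def make_labels_unique(names: list[str]) -> NameTranslationMap:
    """Uniqueness without a length limit (NEXUS labels): duplicates get an
    ``_2``, ``_3``, ... suffix in input order."""
    seen: dict[str, int] = {}
    used: set[str] = set()
    pairs: list[tuple[str, str]] = []
    for name in names:
        if name not in used:
            pairs.append((name, name))
            used.add(name)
            seen[name] = 1
            continue
        n = seen.get(name, 1) + 1
        candidate = f"{name}_{n}"
        while candidate in used:
            n += 1
            candidate = f"{name}_{n}"
        seen[name] = n
        used.add(candidate)
        pairs.append((name, candidate))
    return NameTranslationMap(pairs)
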