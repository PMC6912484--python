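"""Shared fixtures: tiny hand-built pedigrees and simulator helpers."""

import pandas as pd
import pytest

from pedimetrics import Pedigree


def build_pedigree(rows):
    """rows: iterable of (id, sire, dam, sex, birth_year) tuples."""
    return Pedigree(
        pd.DataFrame(rows, columns=["id", "sire", "dam", "sex", "birth_year"])
    )


@pytest.fixture
def trio():
    """Two founders and their offspring."""
    return build_pedigree(
        [
            ("A", None, None, "M", 2000),
            ("B", None, None, "F", 2000),
            ("C", "A", "B", "M", 2005),
        ]
    )


@pytest.fixture
def full_sib_mating():
    """Offspring of a full-sib pair whose parents are unrelated founders."""
    return build_pedigree(
        [
            ("G1", None, None, "M", 1990),
            ("G2", None, None, "F", 1990),
            ("S", "G1", "G2", "M", 1995),
            ("D", "G1", "G2", "F", 1995),
            ("X", "S", "D", "M", 2000),
        ]
    )


@pytest.fixture
def half_sib_mating():
    """Offspring of paternal half sibs."""
    return build_pedigree(
        [
            ("G1", None, None, "M", 1990),
            ("G2", None, None, "F", 1990),
            ("G3", None, None, "F", 1990),
            ("S", "G1", "G2", "M", 1995),
            ("D", "G1", "G3", "F", 1995),
            ("X", "S", "D", "M", 2000),
        ]
    )


@pytest.fixture
def parent_offspring_mating():
    """Sire mated to his own daughter."""
    return build_pedigree(
        [
            ("G1", None, None, "M", 1990),
            ("G2", None, None, "F", 1990),
            ("D", "G1", "G2", "F", 1995),
            ("Y", "G1", "D", "F", 2000),
        ]
    )


def popular_sire_funnel(n_dams=6):
    """Two founders -> one popular sire fathering every reference animal
    on unrelated founder dams: a textbook bottleneck."""
    rows = [
        ("F1", None, None, "M", 1990),
        ("F2", None, None, "F", 1990),
        ("P", "F1", "F2", "M", 1995),
    ]
    for i in range(n_dams):
        rows.append((f"D{i}", None, None, "F", 1995))
        rows.append((f"R{i}", "P", f"D{i}", "F", 2000))
    return build_pedigree(rows), [f"R{i}" for i in range(n_dams)]


def balanced_founder_pairs(n_pairs=4):
    """Unrelated founder pairs, one reference offspring each: founders are
    the ancestors and contributions are perfectly balanced."""
    rows = []
    ref = []
    for i in range(n_pairs):
        rows.append((f"S{i}", None, None, "M", 1990))
        rows.append((f"D{i}", None, None, "F", 1990))
        rows.append((f"C{i}", f"S{i}", f"D{i}", "U", 2000))
        ref.append(f"C{i}")
    return build_pedigree(rows), ref
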