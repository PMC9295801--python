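import pandas as pd
import pytest

import nutriflow as nf
from nutriflow.nutrients import NUTRIENTS


@pytest.fixture(scope="session")
def small_config():
    return nf.WorldConfig(n_nations=8, n_taxa=40, seed=11)


@pytest.fixture(scope="session")
def small_world(small_config):
    return nf.generate_world(small_config)


@pytest.fixture(scope="session")
def small_conc(small_world):
    return nf.resolve_all(
        small_world.taxa, small_world.catch, focal_year=small_world.focal_year
    )


@pytest.fixture(scope="session")
def small_ledger(small_world, small_conc):
    return nf.build_ledger(small_world, small_conc, foc_mode=True)


@pytest.fixture(scope="session")
def small_ledger_nofoc(small_world, small_conc):
    return nf.build_ledger(small_world, small_conc, foc_mode=False)


@pytest.fixture(scope="session")
def oracle_world():
    """10 nations, 30 taxa — the brute-force-oracle comparison world."""
    return nf.generate_world(nf.WorldConfig(n_nations=10, n_taxa=30, seed=42))


@pytest.fixture(scope="session")
def extreme_world():
    base = nf.generate_world(nf.WorldConfig(n_nations=10, n_taxa=60, seed=5))
    return nf.generate_indicator_extremes(base)


def toy_taxa(rows):
    """Build a taxon table from (taxon_id, rank, species, genus, family,
    calcium, iron) tuples; the remaining nutrients get constant values."""
    recs = []
    for tid, rank, sp, gen, fam, ca, fe in rows:
        r = {
            "taxon_id": tid, "rank": rank, "species": sp, "genus": gen,
            "family": fam, "conc_calcium": ca, "conc_iron": fe,
        }
        for n in NUTRIENTS:
            r.setdefault(f"conc_{n}", 1.0 if rank == "species" else None)
        recs.append(r)
    df = pd.DataFrame(recs)
    return df[["taxon_id", "rank", "species", "genus", "family"]
              + [f"conc_{n}" for n in NUTRIENTS]]
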