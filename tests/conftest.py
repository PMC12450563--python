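import datetime

import numpy as np
import pytest

from popshape.pyramid import Bucket, BucketVector
from popshape.studbook_io import IndividualRecord, SpeciesConfig, Studbook
from popshape.synthetic import SimulationConfig, simulate_studbook


def record(iid, sex="female", birth="2000-07-01", death=None, status=None,
           dam=None, sire=None, dam_p=100.0, sire_p=100.0, wild=False,
           region="Europe"):
    """Terse studbook-record builder for fixtures."""
    return IndividualRecord(
        individual_id=iid,
        sex=sex,
        birth_date=datetime.date.fromisoformat(birth),
        death_date=datetime.date.fromisoformat(death) if death else None,
        status=status or ("dead" if death else "alive"),
        dam_id=dam,
        sire_id=sire,
        dam_probability=dam_p,
        sire_probability=sire_p,
        wild_born=wild,
        region=region,
    )


def studbook(records, **config_kwargs):
    return Studbook(records=list(records),
                    species=SpeciesConfig(**config_kwargs))


def bucket_vector(means, sems=None, n_classes=None, total=None,
                  ascribable=True):
    """Bucket vector from plain mean values (sems default to zero)."""
    sems = sems if sems is not None else [0.0] * 5
    n_classes = n_classes if n_classes is not None else [1] * 5
    totals = [int(round(m * n)) for m, n in zip(means, n_classes)]
    buckets = tuple(
        Bucket(mean=m, sem=s, n_classes=n, total=t)
        for m, s, n, t in zip(means, sems, n_classes, totals)
    )
    return BucketVector(
        buckets=buckets,
        total=total if total is not None else sum(totals),
        ascribable=ascribable,
    )


@pytest.fixture(scope="session")
def steady_small():
    """A modest steady-state studbook with its ground truth."""
    config = SimulationConfig(seed=42, years=40, initial_per_sex=150)
    return simulate_studbook(config)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
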