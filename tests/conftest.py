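import datetime as dt

import numpy as np
import pandas as pd
import pytest

from camphen.imageio import RoiStatsTable


def series_to_roistats(dates, gcc, site="testsite", time="12:00:00") -> RoiStatsTable:
    """Wrap a bare (date, gcc) series as a minimal per-image statistics table.

    Used when image formation is not under test: the chromatic remainder is
    split 55/45 between red and blue and the whole-image screening columns
    are set to innocuous values.
    """
    gcc = np.asarray(gcc, dtype=float)
    rows = []
    for d, g in zip(dates, gcc):
        rows.append(
            dict(
                filename="",
                date=d,
                local_std_time=time,
                doy=d.timetuple().tm_yday,
                r_mean=100.0, r_std=1.0, g_mean=110.0, g_std=1.0,
                b_mean=90.0, b_std=1.0,
                rcc=(1 - g) * 0.55, gcc=g, bcc=(1 - g) * 0.45,
                brightness=0.5, darkness=0.2, contrast=0.5,
                haze_degree=20.0, delta=0.1, qc_flag=0,
            )
        )
    return RoiStatsTable(site, "DB", 1000, pd.DataFrame(rows))


@pytest.fixture
def daily_dates():
    def make(n, start=dt.date(2018, 1, 1)):
        return [start + dt.timedelta(days=i) for i in range(n)]

    return make
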