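from datetime import date, datetime, time, timedelta, timezone

import pytest

from isensesleep import ScreenSession

TZ = timezone(timedelta(hours=1))


def dt(day: int, hour: int, minute: int = 0, second: int = 0) -> datetime:
    """Timezone-aware datetime on 2016-01-04 (a Monday) + ``day`` days."""
    return datetime.combine(date(2016, 1, 4) + timedelta(days=day),
                            time(hour, minute, second), tzinfo=TZ)


def make_sessions(pairs):
    """Sessions from ((day, h, m), (day, h, m)) on/off tuples."""
    return [ScreenSession(dt(*on), dt(*off)) for on, off in pairs]


@pytest.fixture
def tz():
    return TZ
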