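import pytest

from cryptsim import RuleParameters, run_linear, run_rosette, run_steady_state

# Printed division-order table for c = 6 (events as parent>child, then the
# total cell count).  The t=15 row's fifth event follows the consecutive-child
# pattern (5>60).
TABLE2 = """
0 | | 1
1 | 0>1 | 2
2 | 0>2 | 3
3 | 0>3 | 4
4 | 0>4 | 5
5 | 0>5 | 6
6 | 0>6 | 7
7 | 0>7 1>8 | 9
8 | 0>9 1>10 2>11 | 12
9 | 0>12 1>13 2>14 3>15 | 16
10 | 0>16 1>17 2>18 3>19 4>20 | 21
11 | 0>21 1>22 2>23 3>24 4>25 5>26 | 27
12 | 0>27 1>28 2>29 3>30 4>31 5>32 6>33 | 34
13 | 0>34 1>35 2>36 3>37 4>38 5>39 6>40 7>41 8>42 | 43
14 | 0>43 1>44 2>45 3>46 4>47 5>48 6>49 7>50 8>51 9>52 10>53 11>54 | 55
15 | 0>55 1>56 2>57 3>58 4>59 5>60 6>61 7>62 8>63 9>64 10>65 11>66 12>67 13>68 14>69 15>70 | 71
"""

# Printed correspondence of maturation period c with the continuous model's
# immature-division rate k2, leading eigenvalue lambda1 and limiting M/I.
TABLE3 = {
    1: (1.0, 1.0, 1.0),
    2: (0.381966, 0.618034, 0.618034),
    3: (0.216757, 0.465571, 0.465571),
    4: (0.144611, 0.380278, 0.380278),
    5: (0.105442, 0.324718, 0.324718),
    6: (0.081338, 0.285199, 0.285199),
}


def parse_table2():
    rows = []
    for line in TABLE2.strip().splitlines():
        t_s, ev_s, n_s = (part.strip() for part in line.split("|"))
        events = [
            tuple(int(v) for v in tok.split(">")) for tok in ev_s.split()
        ]
        rows.append((int(t_s), events, int(n_s)))
    return rows


@pytest.fixture(scope="session")
def table2_rows():
    return parse_table2()


@pytest.fixture(scope="session")
def linear_c6_t15():
    return run_linear(RuleParameters(c=6, T=15))


@pytest.fixture(scope="session")
def rosette_c6_t12():
    return run_rosette(RuleParameters(c=6, T=12))


@pytest.fixture(scope="session")
def steady_run():
    """The bounded steady-state renewal configuration (c=6, L=35, n_wm0=11)."""
    return run_steady_state(
        RuleParameters(c=6, n_wm0=11, L=35, steady_state=True, T=210)
    )
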