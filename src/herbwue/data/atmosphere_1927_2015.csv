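year,ca_ppm,delta13c_air_permil
1927,305.20,-6.70
1928,305.66,-6.71
1929,306.13,-6.71
1930,306.60,-6.72
1931,307.09,-6.72
1932,307.61,-6.73
1933,308.12,-6.74
1934,308.59,-6.74
1935,309.00,-6.75
1936,309.38,-6.75
1937,309.76,-6.76
1938,310.10,-6.77
1939,310.36,-6.77
1940,310.50,-6.78
1941,310.56,-6.79
1942,310.59,-6.79
1943,310.62,-6.80
1944,310.65,-6.81
1945,310.70,-6.81
1946,310.77,-6.82
1947,310.86,-6.83
1948,310.98,-6.83
1949,311.12,-6.84
1950,311.30,-6.85
1951,311.58,-6.86
1952,312.02,-6.87
1953,312.55,-6.88
1954,313.13,-6.88
1955,313.70,-6.89
1956,314.28,-6.90
1957,314.92,-6.91
1958,315.58,-6.93
1959,316.25,-6.94
1960,316.90,-6.95
1961,317.50,-6.96
1962,318.06,-6.98
1963,318.63,-7.00
1964,319.26,-7.02
1965,320.00,-7.04
1966,320.93,-7.06
1967,322.05,-7.08
1968,323.28,-7.10
1969,324.53,-7.13
1970,325.70,-7.15
1971,326.77,-7.18
1972,327.79,-7.20
1973,328.82,-7.23
1974,329.90,-7.26
1975,331.10,-7.29
1976,332.47,-7.32
1977,334.01,-7.36
1978,335.62,-7.39
1979,337.24,-7.42
1980,338.80,-7.45
1981,340.27,-7.48
1982,341.70,-7.51
1983,343.13,-7.54
1984,344.59,-7.57
1985,346.10,-7.60
1986,347.73,-7.63
1987,349.45,-7.66
1988,351.18,-7.69
1989,352.86,-7.72
1990,354.40,-7.75
1991,355.75,-7.78
1992,356.99,-7.80
1993,358.18,-7.83
1994,359.42,-7.85
1995,360.80,-7.88
1996,362.35,-7.90
1997,364.02,-7.92
1998,365.79,-7.95
1999,367.62,-7.97
2000,369.50,-8.00
2001,371.45,-8.03
2002,373.50,-8.06
2003,375.61,-8.09
2004,377.73,-8.12
2005,379.80,-8.15
2006,381.82,-8.18
2007,383.82,-8.21
2008,385.81,-8.24
2009,387.83,-8.27
2010,389.90,-8.30
2011,392.01,-8.33
2012,394.16,-8.36
2013,396.34,-8.38
2014,398.56,-8.41
2015,400.80,-8.44
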