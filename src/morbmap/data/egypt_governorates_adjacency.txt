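# Egypt governorate adjacency (27 nodes), one undirected edge per line:
# "region_a region_b" using the integer ids of egypt_governorates.csv.
# Curated from public administrative maps; desert borders are approximate.
# Substitute your own edge list to change the spatial neighbourhood.
1 4
1 7
1 8
1 14
2 12
2 25
3 5
3 6
3 13
3 26
4 13
4 23
4 26
5 6
6 7
6 9
6 10
7 8
7 13
8 11
9 10
9 12
10 11
10 12
11 12
12 14
12 25
13 26
14 15
14 16
14 24
14 25
15 16
15 17
15 23
17 18
17 23
17 24
18 19
18 23
18 24
19 20
19 23
19 24
20 22
20 23
21 22
21 23
21 24
22 23
22 24
24 25
26 27
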