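# JTT amino-acid exchangeabilities and equilibrium frequencies
# Jones, Taylor & Thornton (1992) CABIOS 8:275-282
# order: A R N D C Q E G H I L K M F P S T W Y V
58.000000
54.000000 45.000000
81.000000 16.000000 528.000000
56.000000 113.000000 34.000000 10.000000
57.000000 310.000000 86.000000 49.000000 9.000000
105.000000 29.000000 58.000000 767.000000 5.000000 323.000000
179.000000 137.000000 81.000000 130.000000 59.000000 26.000000 119.000000
27.000000 328.000000 391.000000 112.000000 69.000000 597.000000 26.000000 23.000000
36.000000 22.000000 47.000000 11.000000 17.000000 9.000000 12.000000 6.000000 16.000000
30.000000 38.000000 12.000000 7.000000 23.000000 72.000000 9.000000 6.000000 56.000000 229.000000
35.000000 646.000000 263.000000 26.000000 7.000000 292.000000 181.000000 27.000000 45.000000 21.000000 14.000000
54.000000 44.000000 30.000000 15.000000 31.000000 43.000000 18.000000 14.000000 33.000000 479.000000 388.000000 65.000000
15.000000 5.000000 10.000000 4.000000 78.000000 4.000000 5.000000 5.000000 40.000000 89.000000 248.000000 4.000000 43.000000
194.000000 74.000000 15.000000 15.000000 14.000000 164.000000 18.000000 24.000000 115.000000 10.000000 102.000000 21.000000 16.000000 17.000000
378.000000 101.000000 503.000000 59.000000 223.000000 53.000000 30.000000 201.000000 73.000000 40.000000 59.000000 47.000000 29.000000 92.000000 285.000000
475.000000 64.000000 232.000000 38.000000 42.000000 51.000000 32.000000 33.000000 46.000000 245.000000 25.000000 103.000000 226.000000 12.000000 118.000000 477.000000
9.000000 126.000000 8.000000 4.000000 115.000000 18.000000 10.000000 55.000000 8.000000 9.000000 52.000000 10.000000 24.000000 53.000000 6.000000 35.000000 12.000000
11.000000 20.000000 70.000000 46.000000 209.000000 24.000000 7.000000 8.000000 573.000000 32.000000 24.000000 8.000000 18.000000 536.000000 10.000000 63.000000 21.000000 71.000000
298.000000 17.000000 16.000000 31.000000 62.000000 20.000000 45.000000 47.000000 11.000000 961.000000 180.000000 14.000000 323.000000 62.000000 23.000000 38.000000 112.000000 25.000000 16.000000

0.076748 0.051691 0.042645 0.051544 0.019803 0.040752 0.061830 0.073152 0.022944 0.053761 0.091904 0.058676 0.023826 0.040126 0.050901 0.068765 0.058565 0.014261 0.032102 0.066005
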