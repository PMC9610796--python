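# JTT amino acid replacement model (Jones, Taylor & Thornton 1992, CABIOS 8:275-282).
# PAML-format: 19 rows of lower-triangle exchangeabilities (amino acid order
# A R N D C Q E G H I L K M F P S T W Y V), then one row of 20 equilibrium frequencies.

58.00 
54.00 45.00 
81.00 16.00 528.00 
56.00 113.00 34.00 10.00 
57.00 310.00 86.00 49.00 9.00 
105.00 29.00 58.00 767.00 5.00 323.00 
179.00 137.00 81.00 130.00 59.00 26.00 119.00 
27.00 328.00 391.00 112.00 69.00 597.00 26.00 23.00 
36.00 22.00 47.00 11.00 17.00 9.00 12.00 6.00 16.00 
30.00 38.00 12.00 7.00 23.00 72.00 9.00 6.00 56.00 229.00 
35.00 646.00 263.00 26.00 7.00 292.00 181.00 27.00 45.00 21.00 14.00 
54.00 44.00 30.00 15.00 31.00 43.00 18.00 14.00 33.00 479.00 388.00 65.00 
15.00 5.00 10.00 4.00 78.00 4.00 5.00 5.00 40.00 89.00 248.00 4.00 43.00 
194.00 74.00 15.00 15.00 14.00 164.00 18.00 24.00 115.00 10.00 102.00 21.00 16.00 17.00 
378.00 101.00 503.00 59.00 223.00 53.00 30.00 201.00 73.00 40.00 59.00 47.00 29.00 92.00 285.00 
475.00 64.00 232.00 38.00 42.00 51.00 32.00 33.00 46.00 245.00 25.00 103.00 226.00 12.00 118.00 477.00 
9.00 126.00 8.00 4.00 115.00 18.00 10.00 55.00 8.00 9.00 52.00 10.00 24.00 53.00 6.00 35.00 12.00 
11.00 20.00 70.00 46.00 209.00 24.00 7.00 8.00 573.00 32.00 24.00 8.00 18.00 536.00 10.00 63.00 21.00 71.00 
298.00 17.00 16.00 31.00 62.00 20.00 45.00 47.00 11.00 961.00 180.00 14.00 323.00 62.00 23.00 38.00 112.00 25.00 16.00 

0.076748 0.051691 0.042645 0.051544 0.019803 0.040752 0.061830 0.073152 0.022944 0.053761 0.091904 0.058676 0.023826 0.040126 0.050901 0.068765 0.058565 0.014261 0.032102 0.066005
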