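wavelength_nm,daylight_6504K
300,72.499484
301,73.072621
302,73.642426
303,74.208843
304,74.771817
305,75.331296
306,75.887229
307,76.439564
308,76.988254
309,77.533252
310,78.074511
311,78.611988
312,79.145639
313,79.675423
314,80.201299
315,80.723229
316,81.241175
317,81.7551
318,82.264971
319,82.770753
320,83.272413
321,83.769921
322,84.263247
323,84.752362
324,85.237239
325,85.717851
326,86.194173
327,86.666183
328,87.133856
329,87.597172
330,88.05611
331,88.51065
332,88.960775
333,89.406468
334,89.847712
335,90.284492
336,90.716795
337,91.144608
338,91.567918
339,91.986715
340,92.400988
341,92.81073
342,93.215931
343,93.616584
344,94.012684
345,94.404225
346,94.791202
347,95.173612
348,95.551453
349,95.924721
350,96.293417
351,96.65754
352,97.01709
353,97.372069
354,97.722479
355,98.068321
356,98.409601
357,98.746322
358,99.078489
359,99.406108
360,99.729184
361,100.047726
362,100.361739
363,100.671233
364,100.976217
365,101.276699
366,101.572689
367,101.864199
368,102.151239
369,102.43382
370,102.711956
371,102.985658
372,103.254941
373,103.519817
374,103.7803
375,104.036406
376,104.28815
377,104.535546
378,104.778611
379,105.017362
380,105.251815
381,105.481987
382,105.707895
383,105.929559
384,106.146996
385,106.360224
386,106.569264
387,106.774133
388,106.974852
389,107.171441
390,107.363919
391,107.552309
392,107.736629
393,107.916902
394,108.093149
395,108.265391
396,108.433651
397,108.59795
398,108.75831
399,108.914755
400,109.067307
401,109.215989
402,109.360823
403,109.501834
404,109.639045
405,109.77248
406,109.902161
407,110.028114
408,110.150362
409,110.26893
410,110.383842
411,110.495122
412,110.602795
413,110.706887
414,110.80742
415,110.904421
416,110.997915
417,111.087926
418,111.17448
419,111.257602
420,111.337317
421,111.413651
422,111.486629
423,111.556276
424,111.622618
425,111.685681
426,111.74549
427,111.80207
428,111.855447
429,111.905648
430,111.952696
431,111.996619
432,112.037442
433,112.07519
434,112.109889
435,112.141564
436,112.170242
437,112.195948
438,112.218707
439,112.238545
440,112.255487
441,112.269559
442,112.280786
443,112.289194
444,112.294808
445,112.297653
446,112.297755
447,112.295139
448,112.289829
449,112.281851
450,112.27123
451,112.257991
452,112.242159
453,112.223758
454,112.202813
455,112.179349
456,112.153391
457,112.124962
458,112.094088
459,112.060792
460,112.025099
461,111.987033
462,111.946618
463,111.903878
464,111.858837
465,111.811517
466,111.761945
467,111.710141
468,111.656131
469,111.599937
470,111.541583
471,111.481092
472,111.418486
473,111.353789
474,111.287023
475,111.218211
476,111.147376
477,111.07454
478,110.999726
479,110.922955
480,110.84425
481,110.763632
482,110.681123
483,110.596746
484,110.510522
485,110.422472
486,110.332617
487,110.240979
488,110.147579
489,110.052438
490,109.955576
491,109.857015
492,109.756774
493,109.654875
494,109.551338
495,109.446182
496,109.339429
497,109.231097
498,109.121207
499,109.009778
500,108.89683
501,108.782382
502,108.666454
503,108.549065
504,108.430233
505,108.309977
506,108.188317
507,108.065271
508,107.940857
509,107.815093
510,107.687999
511,107.559591
512,107.429889
513,107.298909
514,107.166669
515,107.033187
516,106.898481
517,106.762567
518,106.625462
519,106.487185
520,106.347751
521,106.207178
522,106.065481
523,105.922678
524,105.778785
525,105.633817
526,105.487792
527,105.340725
528,105.192632
529,105.043528
530,104.89343
531,104.742352
532,104.590311
533,104.43732
534,104.283396
535,104.128553
536,103.972805
537,103.816169
538,103.658658
539,103.500286
540,103.341068
541,103.181019
542,103.020151
543,102.85848
544,102.696019
545,102.532781
546,102.368781
547,102.204031
548,102.038545
549,101.872337
550,101.705418
551,101.537804
552,101.369505
553,101.200535
554,101.030907
555,100.860632
556,100.689724
557,100.518195
558,100.346056
559,100.173321
560,100.0
561,99.826106
562,99.65165
563,99.476644
564,99.301099
565,99.125028
566,98.94844
567,98.771348
568,98.593761
569,98.415692
570,98.237151
571,98.058149
572,97.878696
573,97.698803
574,97.51848
575,97.337738
576,97.156587
577,96.975037
578,96.793097
579,96.610779
580,96.428091
581,96.245043
582,96.061645
583,95.877907
584,95.693837
585,95.509446
586,95.324742
587,95.139734
588,94.954432
589,94.768844
590,94.58298
591,94.396848
592,94.210456
593,94.023813
594,93.836928
595,93.649809
596,93.462465
597,93.274902
598,93.087131
599,92.899158
600,92.710992
601,92.52264
602,92.33411
603,92.14541
604,91.956548
605,91.76753
606,91.578365
607,91.38906
608,91.199621
609,91.010057
610,90.820374
611,90.630579
612,90.44068
613,90.250682
614,90.060593
615,89.87042
616,89.680169
617,89.489847
618,89.29946
619,89.109015
620,88.918517
621,88.727974
622,88.537391
623,88.346775
624,88.156131
625,87.965465
626,87.774784
627,87.584093
628,87.393399
629,87.202705
630,87.012019
631,86.821346
632,86.630691
633,86.44006
634,86.249457
635,86.058889
636,85.868361
637,85.677877
638,85.487443
639,85.297064
640,85.106745
641,84.91649
642,84.726305
643,84.536194
644,84.346163
645,84.156214
646,83.966355
647,83.776588
648,83.586918
649,83.39735
650,83.207888
651,83.018537
652,82.8293
653,82.640182
654,82.451187
655,82.26232
656,82.073583
657,81.884981
658,81.696519
659,81.508199
660,81.320027
661,81.132005
662,80.944137
663,80.756427
664,80.568878
665,80.381495
666,80.19428
667,80.007237
668,79.82037
669,79.633682
670,79.447176
671,79.260855
672,79.074724
673,78.888784
674,78.703039
675,78.517493
676,78.332148
677,78.147007
678,77.962073
679,77.777349
680,77.592838
681,77.408544
682,77.224467
683,77.040613
684,76.856982
685,76.673578
686,76.490404
687,76.307461
688,76.124753
689,75.942283
690,75.760051
691,75.578062
692,75.396317
693,75.214819
694,75.033569
695,74.852571
696,74.671827
697,74.491338
698,74.311108
699,74.131137
700,73.951429
701,73.771985
702,73.592807
703,73.413897
704,73.235258
705,73.056891
706,72.878798
707,72.700981
708,72.523442
709,72.346182
710,72.169204
711,71.992508
712,71.816098
713,71.639974
714,71.464138
715,71.288592
716,71.113337
717,70.938376
718,70.763708
719,70.589337
720,70.415263
721,70.241488
722,70.068013
723,69.894839
724,69.721969
725,69.549403
726,69.377143
727,69.205189
728,69.033544
729,68.862208
730,68.691183
731,68.520469
732,68.350069
733,68.179983
734,68.010211
735,67.840756
736,67.671619
737,67.502799
738,67.334299
739,67.16612
740,66.998261
741,66.830725
742,66.663512
743,66.496624
744,66.33006
745,66.163821
746,65.99791
747,65.832326
748,65.66707
749,65.502143
750,65.337545
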