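wavelength_nm,value
450.0,1.78158091
455.0,1.74698706
460.0,1.67154326
465.0,1.51893397
470.0,1.29516835
475.0,1.04491407
480.0,0.81027531
485.0,0.61576068
490.0,0.46637669
495.0,0.35505567
500.0,0.27144376
505.0,0.20705612
510.0,0.15647916
515.0,0.11656798
520.0,0.08535398
525.0,0.06135088
530.0,0.04326598
535.0,0.02993125
540.0,0.02031109
545.0,0.01351965
550.0,0.00882715
555.0,0.00565325
560.0,0.00355139
565.0,0.00218837
570.0,0.00132271
575.0,0.00078421
580.0,0.00045606
585.0,0.00026016
590.0,0.00014557
595.0,7.99e-05
600.0,4.301e-05
605.0,2.271e-05
610.0,1.177e-05
615.0,5.98e-06
620.0,2.98e-06
625.0,1.46e-06
630.0,7e-07
635.0,3.3e-07
640.0,1.5e-07
645.0,7e-08
650.0,3e-08
655.0,1e-08
660.0,1e-08
665.0,0.0
670.0,0.0
675.0,0.0
680.0,0.0
685.0,0.0
690.0,0.0
695.0,0.0
700.0,0.0
705.0,0.0
710.0,0.0
715.0,0.0
720.0,0.0
725.0,0.0
730.0,0.0
735.0,0.0
740.0,0.0
745.0,0.0
750.0,0.0
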