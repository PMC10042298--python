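wavelength_nm,value
450.0,0.00051854
455.0,0.00085834
460.0,0.00139656
465.0,0.0022335
470.0,0.00351109
475.0,0.0054254
480.0,0.00824057
485.0,0.0123034
490.0,0.01805678
495.0,0.02605018
500.0,0.03694408
505.0,0.05150543
510.0,0.07059072
515.0,0.09511372
520.0,0.12599604
525.0,0.16410025
530.0,0.21014758
535.0,0.26462506
540.0,0.32768986
545.0,0.39908076
550.0,0.47804885
555.0,0.56331897
560.0,0.65309255
565.0,0.7450985
570.0,0.83669397
575.0,0.92501042
580.0,1.0071342
585.0,1.08030497
590.0,1.14211183
595.0,1.19066558
600.0,1.22472768
605.0,1.24378107
610.0,1.24803531
615.0,1.23836662
620.0,1.21620163
625.0,1.18336061
630.0,1.14188014
635.0,1.09383657
640.0,1.04118991
645.0,0.9856632
650.0,0.92866654
655.0,0.87126786
660.0,0.81420633
665.0,0.75793937
670.0,0.70271119
675.0,0.64862983
680.0,0.59574105
685.0,0.54408967
690.0,0.49376269
695.0,0.44491185
700.0,0.39775684
705.0,0.35257251
710.0,0.30966524
715.0,0.26934371
720.0,0.23188952
725.0,0.19753145
730.0,0.16642646
735.0,0.13864872
740.0,0.11418679
745.0,0.09294822
750.0,0.07476987
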