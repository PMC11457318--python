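('PCE_A_Chro7G0000400.1':0.08333007812500001,'PCE_A_Chro7G0000800.1':0.06333658854166666,('PCE_F_Chro1G0001200.3':0.04634765624999999,(('PCE_A_Chro7G0000200.2':0.0736393229166667,'PCE_F_Chro1G0000600.2':0.06636067708333332):0.0522536892361111,(('PCE_A_Chro7G0000900.2':0.05124131944444443,'PCE_F_Chro1G0000400.1':0.08875868055555558):0.03302246093750002,(((('PCE_A_Chro1G0000800.1':0.03699275362318844,'PCE_F_Chro1G0000900.1':0.06967391304347823):0.06508285984848486,('PCE_F_Chro1G0000900.2':0.030824652777777743,'PCE_F_Chro1G0001200.2':0.08250868055555559):0.022417140151515136):0.04998119212962962,('PCE_A_Chro7G0000100.1':0.07182291666666664,'PCE_F_Chro7G0000100.2':0.058177083333333365):0.035018807870370344):0.06963736979166667,((('PCE_A_Chro1G0001200.1':0.08460286458333331,('PCE_F_Chro7G0000600.1':0.04763480392156866,('PCE_F_Chro1G0000700.2':0.05787280701754384,('PCE_A_Chro7G0000100.2':0.07659090909090906,'PCE_F_Chro1G0000700.1':0.08674242424242427):0.03212719298245616):0.039031862745098):0.013313802083333368):0.029508928571428547,(('PCE_A_Chro7G0000200.1':0.08164583333333335,'PCE_F_Chro7G0000500.1':0.03168749999999998):0.06579513888888888,('PCE_F_Chro7G0000600.2':0.05921296296296293,(('PCE_A_Chro7G0000900.1':0.03466666666666667,'PCE_F_Chro1G0000600.1':0.04866666666666666):0.06236111111111108,('PCE_F_Chro1G0001200.1':0.0592361111111111,'PCE_F_Chro7G0000100.1':0.0707638888888889):0.05263888888888891):0.0416203703703704):0.03191319444444446):0.02543898809523809):0.11701543898809524,('PCE_A_Chro7G0000700.1':0.03456330128205128,'PCE_F_Chro7G0000500.2':0.03877003205128205):0.10009393601190475):0.024574869791666662):0.030926106770833343):0.03393771701388889):0.022639973958333344):0.01198567708333334);
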